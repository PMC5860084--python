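import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hocmine.corpus_io import SentenceRecord
from hocmine.features import (
    EmptyClassError,
    FeatureExtractor,
    FeatureKey,
    FeatureSpace,
    GazetteerTagger,
    VerbClassLexicon,
    build_matrix,
    extract_entities,
    extract_lbow,
    extract_metadata,
    extract_ngrams,
    extract_semantic_distance,
    extract_verb_classes,
    sd_bin,
    select_features,
    vectorize,
)


def sent(tokens, pmid="1", index=0, labels=(), mesh=(), chem=()):
    return SentenceRecord(
        pmid=pmid,
        index=index,
        text=" ".join(tokens),
        tokens=list(tokens),
        lemmas=[t.lower() for t in tokens],
        gold_labels=set(labels),
        mesh_terms=list(mesh),
        chemicals=list(chem),
    )


class TestLbow:
    def test_set_semantics_and_casefold(self):
        keys = extract_lbow(sent(["Cell", "cycle", "arrest", "arrest"]))
        assert keys == {
            FeatureKey("LBOW", "cell"),
            FeatureKey("LBOW", "cycle"),
            FeatureKey("LBOW", "arrest"),
        }

    def test_all_stopwords_empty(self):
        assert extract_lbow(sent(["The", "was", "of"])) == set()

    def test_uppercase_token_lowercased(self):
        assert extract_lbow(sent(["P53"])) == {FeatureKey("LBOW", "p53")}


class TestNgrams:
    @pytest.mark.parametrize(
        "tokens,expected_count",
        [(["a"], 0), (["a", "b"], 1), (["a", "b", "c"], 3), (["a", "b", "c", "d"], 5)],
    )
    def test_counts(self, tokens, expected_count):
        assert len(extract_ngrams(sent(tokens))) == expected_count

    def test_joined_with_underscore(self):
        keys = extract_ngrams(sent(["a", "b", "c"]))
        assert keys == {
            FeatureKey("NGRAM", "a_b"),
            FeatureKey("NGRAM", "b_c"),
            FeatureKey("NGRAM", "a_b_c"),
        }

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from("abcdefgh"), min_size=0, max_size=12))
    def test_count_formula_before_dedup(self, tokens):
        n = len(tokens)
        expected = max(0, n - 1) + max(0, n - 2)
        grams = [
            tuple(tokens[i : i + k]) for k in (2, 3) for i in range(n - k + 1)
        ]
        assert len(grams) == expected
        assert len(extract_ngrams(sent(tokens))) == len(set(grams))


class TestVerbClasses:
    lexicon = VerbClassLexicon({"induce": {"VC7"}, "trigger": {"VC7"}})

    def test_lookup(self):
        assert extract_verb_classes(sent(["induce"]), self.lexicon) == {
            FeatureKey("VC", "VC7")
        }

    def test_no_hits(self):
        assert extract_verb_classes(sent(["banana"]), self.lexicon) == set()

    def test_two_lemmas_same_class_one_key(self):
        keys = extract_verb_classes(sent(["induce", "trigger"]), self.lexicon)
        assert keys == {FeatureKey("VC", "VC7")}


class TestEntities:
    def test_type_and_surface_keys(self):
        tagger = GazetteerTagger.default()
        keys = extract_entities(sent(["p53", "binds"]), tagger)
        assert keys == {FeatureKey("NE", "Protein"), FeatureKey("NE", "Protein:p53")}

    def test_no_entities(self):
        tagger = GazetteerTagger.default()
        assert extract_entities(sent(["banana", "split"]), tagger) == set()

    def test_two_proteins_share_type_key(self):
        tagger = GazetteerTagger.default()
        keys = extract_entities(sent(["p53", "egfr"]), tagger)
        assert len([k for k in keys if k.value == "Protein"]) == 1
        assert len(keys) == 3

    def test_length_contract_enforced(self):
        class Broken:
            def tag(self, tokens):
                return ["O"]

        with pytest.raises(ValueError, match="tags"):
            extract_entities(sent(["a", "b"]), Broken())


class TestMetadata:
    def test_mesh_and_chem(self):
        keys = extract_metadata(sent(["x"], mesh=["Lung Neoplasms"], chem=["Cisplatin"]))
        assert keys == {
            FeatureKey("MESH", "Lung Neoplasms"),
            FeatureKey("CHEM", "Cisplatin"),
        }

    def test_empty(self):
        assert extract_metadata(sent(["x"])) == set()

    def test_duplicates_collapse(self):
        keys = extract_metadata(sent(["x"], mesh=["Humans", "Humans"]))
        assert len(keys) == 1


class _StubEmbedding:
    """Fixed vectors: wa || label A, wb orthogonal."""

    def __init__(self):
        self.vecs = {"wa": np.array([1.0, 0.0]), "wb": np.array([0.0, 1.0])}
        self.labels = {"3": np.array([2.0, 0.0])}

    def similarity(self, lemma, code):
        w = self.vecs.get(lemma)
        v = self.labels.get(code)
        if w is None or v is None:
            return None
        return float(w @ v / (np.linalg.norm(w) * np.linalg.norm(v)))


class TestSemanticDistance:
    def test_out_of_vocabulary_empty(self):
        assert extract_semantic_distance(sent(["zzz"]), _StubEmbedding(), "3") == set()

    def test_identical_direction_maps_to_top_bin(self):
        keys = extract_semantic_distance(sent(["wa"]), _StubEmbedding(), "3")
        assert keys == {FeatureKey("SD", "3|bin9")}

    def test_orthogonal_maps_to_bin_containing_zero(self):
        keys = extract_semantic_distance(sent(["wb"]), _StubEmbedding(), "3")
        assert keys == {FeatureKey("SD", f"3|bin{sd_bin(0.0)}")}

    def test_max_over_lemmas(self):
        keys = extract_semantic_distance(sent(["wa", "wb"]), _StubEmbedding(), "3")
        assert keys == {FeatureKey("SD", "3|bin9")}

    def test_label_missing_from_model_is_error(self):
        from hocmine.embedding import EmbeddingConfig, EmbeddingModel

        model = EmbeddingModel(["wa"], np.ones((1, 2)), EmbeddingConfig(dim=2))
        with pytest.raises(ValueError, match="missing from the embedding"):
            extract_semantic_distance(sent(["wa"]), model, "3")

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    def test_bins_partition_interval(self, sim):
        idx = sd_bin(sim, bins=10)
        assert 0 <= idx <= 9
        lo = -1.0 + 2.0 * idx / 10
        hi = lo + 0.2
        # edge attribution may move a value one float ulp across a boundary
        assert lo - 1e-9 <= sim <= hi + 1e-9


class TestSelection:
    def _corpus(self):
        # pmid A is positive for 3 (via 3.1); pmid B negative.
        sents = []
        for i in range(6):
            sents.append(sent(["hot", "shared"], pmid="A", index=i, labels={"3.1"} if i == 0 else ()))
        for i in range(6):
            sents.append(sent(["cold", "shared"], pmid="B", index=i))
        return sents

    def test_positive_abstract_restriction(self, taxonomy):
        extractor = FeatureExtractor(kinds=("LBOW",))
        space = select_features(self._corpus(), "3", taxonomy, extractor, min_count=1)
        values = {k.value for k in space.index}
        # "cold" occurs only in the negative abstract: never a candidate.
        assert "hot" in values and "shared" in values and "cold" not in values

    @pytest.mark.parametrize("count,included", [(4, False), (5, True)])
    def test_min_count_boundary(self, taxonomy, count, included):
        sents = [
            sent(["rare"] if i < count else ["filler", "pad"], pmid="A", index=i,
                 labels={"3"} if i == 0 else ())
            for i in range(8)
        ]
        # keep "rare" in the positive abstract so it is a candidate
        extractor = FeatureExtractor(kinds=("LBOW",))
        space = select_features(sents, "3", taxonomy, extractor, min_count=5)
        assert (FeatureKey("LBOW", "rare") in space.index) is included

    def test_max_count_ceiling(self, taxonomy):
        sents = [
            sent(["common", f"u{i}"], pmid="A", index=i, labels={"3"} if i == 0 else ())
            for i in range(10)
        ]
        extractor = FeatureExtractor(kinds=("LBOW",))
        space = select_features(sents, "3", taxonomy, extractor, min_count=1, max_count=9)
        assert FeatureKey("LBOW", "common") not in space.index

    def test_no_positives_raises(self, taxonomy):
        sents = [sent(["a", "b"], pmid="A", index=0)]
        with pytest.raises(EmptyClassError):
            select_features(sents, "3", taxonomy, FeatureExtractor(kinds=("LBOW",)))

    def test_unfiltered_selection_equals_bruteforce_positive_keys(self, taxonomy, realistic_corpus):
        _, sentences = realistic_corpus
        sample = sentences[:400]
        extractor = FeatureExtractor(kinds=("LBOW", "NGRAM"))
        try:
            space = select_features(
                sample, "3", taxonomy, extractor, min_count=1, max_count=10**9
            )
        except EmptyClassError:
            pytest.skip("no positives for node 3 in this sample")
        positive_pmids = set()
        for s in sample:
            closed = set(s.gold_labels)
            for lab in s.gold_labels:
                closed.update(taxonomy.ancestors(lab))
            if "3" in closed:
                positive_pmids.add(s.pmid)
        brute = set()
        for s in sample:
            if s.pmid in positive_pmids:
                brute |= extractor.keys(s)
        assert set(space.index) == brute


class TestVectorize:
    def test_unindexed_keys_dropped(self, taxonomy):
        space = FeatureSpace(
            node_code="3",
            index={FeatureKey("LBOW", "hot"): 0},
            min_count=1,
            max_count={"LBOW": 500},
        )
        extractor = FeatureExtractor(kinds=("LBOW",))
        vec = vectorize(sent(["unknown", "words"]), space, extractor)
        assert vec.columns == frozenset() and vec.dimension == 1

    def test_deterministic(self, taxonomy):
        space = FeatureSpace(
            node_code="3",
            index={FeatureKey("LBOW", "hot"): 0, FeatureKey("LBOW", "cold"): 1},
            min_count=1,
            max_count={"LBOW": 500},
        )
        extractor = FeatureExtractor(kinds=("LBOW",))
        s = sent(["hot", "cold", "hot"])
        assert vectorize(s, space, extractor) == vectorize(s, space, extractor)

    def test_union_of_per_extractor_vectors(self):
        s = sent(["p53", "induce", "apoptosis"], mesh=["Humans"])
        lexicon = VerbClassLexicon({"induce": {"VC7"}})
        full = FeatureExtractor(kinds=("LBOW", "VC", "MESH"), lexicon=lexicon)
        union = set()
        for kind in ("LBOW", "VC", "MESH"):
            union |= FeatureExtractor(kinds=(kind,), lexicon=lexicon).keys(s)
        assert full.keys(s) == union

    def test_space_json_round_trip(self, tmp_path):
        space = FeatureSpace(
            node_code="3.1",
            index={FeatureKey("LBOW", "hot"): 0, FeatureKey("NGRAM", "a_b"): 1},
            min_count=5,
            max_count={k: 500 for k in ("LBOW", "NGRAM", "VC", "NE", "MESH", "CHEM", "SD")},
        )
        path = tmp_path / "space.json"
        space.to_json(path)
        again = FeatureSpace.from_json(path)
        assert again == space

    def test_build_matrix_binary(self):
        from hocmine.features import SparseVector

        vecs = [SparseVector(columns=frozenset(c), dimension=4) for c in [{0, 2}, set(), {3}]]
        X = build_matrix(vecs)
        assert X.shape == (3, 4)
        assert X.toarray().tolist() == [
            [1, 0, 1, 0],
            [0, 0, 0, 0],
            [0, 0, 0, 1],
        ]
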