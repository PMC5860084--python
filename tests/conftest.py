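import pytest

from hocmine.classify import PipelineConfig
from hocmine.embedding import EmbeddingConfig
from hocmine.synthetic import SyntheticSpec, generate_corpus, generate_separable_corpus
from hocmine.taxonomy import load_default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return load_default_taxonomy()


@pytest.fixture(scope="session")
def small_separable(taxonomy):
    """Small linearly separable corpus: 740 sentences, 20 per node."""
    return generate_separable_corpus(taxonomy, 740, seed=42)


@pytest.fixture(scope="session")
def realistic_corpus(taxonomy):
    """Realistic-shape synthetic corpus (~1800 sentences, 75% unlabeled)."""
    spec = SyntheticSpec(n_abstracts=300, seed=7)
    return generate_corpus(spec, taxonomy)


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline config scaled for unit tests (small embedding, short grid)."""
    return PipelineConfig(
        seed=3,
        C_grid=(1.0,),
        inner_folds=2,
        embedding=EmbeddingConfig(dim=20, epochs=3, seed=0),
    )


MEDLINE_XML = """<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>101</PMID>
      <Article>
        <ArticleTitle>First article</ArticleTitle>
        <Abstract>
          <AbstractText>P53 induces apoptosis in tumor cells. The effect, i.e. cell death, was dose dependent.</AbstractText>
        </Abstract>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName>Apoptosis</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName>Lung Neoplasms</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName>Humans</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName>Cell Line</DescriptorName></MeshHeading>
      </MeshHeadingList>
      <ChemicalList>
        <Chemical><NameOfSubstance>Cisplatin</NameOfSubstance></Chemical>
        <Chemical><NameOfSubstance>Aspirin</NameOfSubstance></Chemical>
      </ChemicalList>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>102</PMID>
      <Article>
        <ArticleTitle>No abstract here</ArticleTitle>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>103</PMID>
      <Article>
        <ArticleTitle>Second article</ArticleTitle>
        <Abstract>
          <AbstractText>VEGF drives angiogenesis. Invasion was observed.</AbstractText>
        </Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture()
def medline_file(tmp_path):
    path = tmp_path / "medline.xml"
    path.write_text(MEDLINE_XML, encoding="utf-8")
    return path
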