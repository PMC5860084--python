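"""Reference per-class benchmark statistics for the hallmark taxonomy.

The shipped table records, for each of the 37 taxonomy classes, the number
of positively annotated sentences in the original annotated corpus, the
number of PubMed sentences the classifier of record labelled positive, the
size of the selected feature set, and the reported precision, recall, F1
and accuracy (percent).  It is used for arithmetic self-consistency checks
(recomputing F1 from precision/recall, and macro averages from per-class
rows) — not as training data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_benchmark_table"]


def load_benchmark_table() -> pd.DataFrame:
    """Per-class reference statistics, indexed by taxonomy code."""
    ref = resources.files("hocmine.data").joinpath("benchmark_stats.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", dtype={"code": str})
    return table.set_index("code")
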