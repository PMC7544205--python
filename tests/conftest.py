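import numpy as np
import pandas as pd
import pytest

from rnptools import GenomeAnnotation, LfqMatrix, Transcript


def make_lfq(values: np.ndarray, n_bait: int, n_ctrl: int,
             ids=None, mw=None, condition="c1", log_transformed=False) -> LfqMatrix:
    """Build a small LfqMatrix from a plain array (NaN = missing)."""
    values = np.asarray(values, float)
    n = values.shape[0]
    ids = list(ids) if ids is not None else [f"P{i + 1}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "role": ["bait"] * n_bait + ["control"] * n_ctrl,
            "condition": condition,
            "replicate": list(range(1, n_bait + 1)) + list(range(1, n_ctrl + 1)),
        },
        index=pd.Index([f"{condition}_bait_r{r + 1}" for r in range(n_bait)]
                       + [f"{condition}_ctrl_r{r + 1}" for r in range(n_ctrl)],
                       name="sample"),
    )
    mw = pd.Series(mw if mw is not None else np.full(n, 50.0), index=ids)
    return LfqMatrix(values=pd.DataFrame(values, index=ids,
                                         columns=samples.index),
                     samples=samples, mw_kda=mw,
                     log_transformed=log_transformed)


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two multiexonic transcripts (one per strand) and one monoexonic."""
    return GenomeAnnotation([
        Transcript("txP", "geneP", "chr1", "+",
                   [(1000, 1300), (1500, 1750), (2000, 2400)]),
        Transcript("txM", "geneM", "chr1", "-",
                   [(5000, 5300), (5500, 5750), (6000, 6400)]),
        Transcript("txMono", "geneMono", "chr1", "+", [(8000, 8500)]),
    ])
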