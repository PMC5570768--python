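"""Bundled example data."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_sle_pcorr"]


def load_sle_pcorr() -> pd.DataFrame:
    """Reference three-batch p(corr) profile table (SLE versus controls).

    Per-batch OPLS-DA p(corr) loadings for 73 identified plasma metabolites
    from a three-batch GC-TOF-MS case/control comparison of systemic lupus
    erythematosus patients with population controls, together with the
    reported combined-profile average p(corr) and average confidence
    interval for the sign-consistent metabolites (blank elsewhere).

    Indexed by compound name; columns: ``hmdb``, ``compound_class``,
    ``pcorr_batch1..3``, ``avg_pcorr``, ``avg_ci``.
    """
    with resources.files("metabatch.data").joinpath(
            "sle_three_batch_pcorr.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, index_col="compound")
    return df
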