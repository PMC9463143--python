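"""HRDE-1 vs CSR-1 IP enrichment ratios and their four-class categorization.

The ratio ``log2((hrde_rpm + rho) / (csr_rpm + rho))`` separates transcripts
whose 22G-RNAs load predominantly onto the silencing Argonaute HRDE-1 from
those loaded onto the licensing Argonaute CSR-1.  Class boundaries follow
the published anchors: < -2.8 highly CSR-1 favored; [-2.8, -1.82] CSR-1
favored; (-1.82, 0] slightly CSR-1 favored; > 0 HRDE-1 favored.  The four
classes partition the real line.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .classify import NormalizedTable
from .errors import DataError

RATIO_CLASSES = (
    "highly_csr_favored",
    "csr_favored",
    "slightly_csr_favored",
    "hrde_favored",
)

DEFAULT_PSEUDOCOUNT = 0.1  # RPM; keeps zero-count genes finite in boxplots


def classify_ratio(log2_ratio) -> np.ndarray | str:
    """Map log2(HRDE-1 IP / CSR-1 IP) values to the four ratio classes."""
    arr = np.asarray(log2_ratio, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("classify_ratio: non-finite log2 ratio")
    out = np.select(
        [arr < -2.8, arr <= -1.82, arr <= 0.0],
        ["highly_csr_favored", "csr_favored", "slightly_csr_favored"],
        default="hrde_favored",
    )
    if np.isscalar(log2_ratio) or arr.ndim == 0:
        return str(out)
    return out


def compute_ratio(
    hrde: NormalizedTable | Mapping[str, float] | pd.Series,
    csr: NormalizedTable | Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene HRDE-1/CSR-1 RPM ratio records over ``gene_set``.

    Accepts normalized tables (22G antisense RPM is used) or plain
    feature -> RPM mappings; genes absent from either side count as 0 RPM.
    """
    genes = sorted(set(gene_set))
    if not genes:
        raise DataError("gene_set is empty")
    h = _as_series(hrde).reindex(genes).fillna(0.0)
    c = _as_series(csr).reindex(genes).fillna(0.0)
    if pseudocount <= 0 and ((h == 0) | (c == 0)).any():
        raise DataError(
            "zero RPM with zero pseudocount would produce infinite ratios"
        )
    log2_ratio = np.log2((h.values + pseudocount) / (c.values + pseudocount))
    return pd.DataFrame(
        {
            "feature_id": genes,
            "hrde_rpm": h.values,
            "csr_rpm": c.values,
            "log2_ratio": log2_ratio,
            "ratio_class": classify_ratio(log2_ratio),
        }
    )


def _as_series(x) -> pd.Series:
    if isinstance(x, NormalizedTable):
        return x.series("g22_antisense", "antisense")
    return pd.Series(x, dtype=float)
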