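"""Count normalization and a simplified differential-expression stage.

This is deliberately NOT a negative-binomial GLM engine: counts are
normalized by median-of-ratios size factors (the standard library-size
estimator for RNA-seq count matrices), and group comparison is a Welch
two-sided t-test on log2(normalized count + 1) with Benjamini-Hochberg
adjustment.  The stand-in is documented as such and validated against
planted truth on synthetic data; its role in the pipeline is only to supply
a gene list with q-values for the EC-integration stage, not to reproduce
any particular DE engine's per-gene statistics.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .metabolomics import _welch_on_logs, bh_adjust, signed_fold_change

__all__ = ["size_factors", "de_test", "DEG_COLUMNS"]

DEG_COLUMNS = ["gene", "base_mean", "fold_change", "log2fc", "p_value", "q_value"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    For each gene expressed in every sample, the ratio of each sample's count
    to the gene's geometric mean is formed; a sample's factor is the median
    of its ratios.  An all-equal matrix yields factors of exactly 1.
    Requires at least one gene with a nonzero count in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene has nonzero counts in every sample")
    log_counts = np.log(mat[expressed])
    log_geo_means = log_counts.mean(axis=1, keepdims=True)
    log_ratios = log_counts - log_geo_means
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def de_test(
    counts: pd.DataFrame, sample_groups: Mapping[str, str], pseudo: float = 1.0
) -> pd.DataFrame:
    """Differential expression across control/treated sample groups.

    ``counts`` is gene x sample with non-negative integer counts and
    ``sample_groups`` maps each sample column to "control" or "treated".
    Counts are size-factor normalized, then each gene gets a Welch t-test on
    log2(normalized + pseudo).  Genes whose p-value is undefined (degenerate
    groups) are flagged with NaN rather than dropped.

    Output columns: gene, base_mean, fold_change (signed display), log2fc,
    p_value, q_value.
    """
    control = [s for s, g in sample_groups.items() if g == "control"]
    treated = [s for s, g in sample_groups.items() if g == "treated"]
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need at least two samples per group")
    missing = [s for s in control + treated if s not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from count matrix: {missing}")
    sf = size_factors(counts[control + treated])
    norm = counts[control + treated].to_numpy(dtype=float) / sf.to_numpy()
    norm_df = pd.DataFrame(norm, index=counts.index, columns=control + treated)
    p, log2fc = _welch_on_logs(
        norm_df[control].to_numpy(), norm_df[treated].to_numpy(), pseudo
    )
    out = pd.DataFrame(
        {
            "gene": counts.index,
            "base_mean": norm_df.mean(axis=1).to_numpy(),
            "fold_change": signed_fold_change(log2fc),
            "log2fc": log2fc,
            "p_value": p,
            "q_value": bh_adjust(p),
        }
    ).reset_index(drop=True)
    return out[DEG_COLUMNS]
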