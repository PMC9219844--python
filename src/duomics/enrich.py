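"""Pathway activity scoring from annotated differential features.

The universe is the set of features with a rank-1 compound annotation; the
"significant" subset is thresholded on the per-feature p-value.  For each
pathway, enrichment of significant features among pathway members is scored
two ways:

* a one-sided (enrichment) Fisher exact test on the 2x2 table
  (significant x pathway-member) over the annotated universe — one-sided so
  that its ordering agrees with the enrichment-directed permutation null
  (the standalone :func:`fisher_exact_2x2` primitive is two-sided) — and
* an empirical permutation p-value: B random significant sets of the same
  size are drawn from the universe (resampling feature ids, preserving the
  annotation structure) and the pathway's hit count compared, with the
  add-one rule p = (1 + #{permuted >= observed}) / (B + 1), so an empirical
  p of exactly zero is impossible.

A pathway's direction is summarized as the mean signed fold-change of its
significant member features (positive = up-regulated pathway).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .metabolomics import signed_fold_change

__all__ = ["ContingencyTable", "fisher_exact_2x2", "PathwayResult", "pathway_activity"]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows significant/non-significant, columns in/out of pathway."""

    sig_in: int
    sig_out: int
    nonsig_in: int
    nonsig_out: int

    def as_array(self) -> np.ndarray:
        return np.array([[self.sig_in, self.sig_out], [self.nonsig_in, self.nonsig_out]])


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    The two-sided p sums hypergeometric probabilities of all tables (with the
    observed margins) whose probability does not exceed the observed table's.
    """
    if isinstance(table, ContingencyTable):
        arr = table.as_array()
    else:
        arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("contingency cells must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("contingency cells must be integers")
        arr = np.round(arr).astype(int)
    p = stats.fisher_exact(arr, alternative="two-sided")[1]
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


@dataclass(frozen=True)
class PathwayResult:
    """Scored activity of one pathway."""

    pathway: str
    n_pathway_compounds_hit: int  # annotated universe features in the pathway
    n_significant_hits: int  # of which significant
    fisher_p: float  # one-sided enrichment p
    empirical_p: float
    direction_summary: float  # mean signed fold-change of significant members
    members: tuple
    flagged: bool = False  # no annotated members in the universe


def pathway_activity(
    annotated: pd.DataFrame,
    pathway_compounds: Mapping[str, set],
    sig_threshold: float = 0.001,
    B: int = 999,
    seed: int = 0,
    p_column: str = "p_value",
) -> list[PathwayResult]:
    """Score every pathway against the annotated feature universe.

    ``annotated`` needs columns id, compound, signed_fold_change (or log2fc)
    and the p-value column; ``pathway_compounds`` maps pathway name to its
    compound set.  Deterministic given ``seed``.  Results are sorted by
    (empirical_p, fisher_p, pathway).
    """
    if B < 99:
        raise ValueError("need at least 99 permutations")
    if not pathway_compounds:
        raise ValueError("no pathways given")
    universe = annotated[
        annotated["compound"].notna() & (annotated["compound"] != "unannotated")
    ].reset_index(drop=True)
    n = len(universe)
    sig_mask = (universe[p_column] < sig_threshold).to_numpy()
    k = int(sig_mask.sum())

    if "signed_fold_change" in universe.columns:
        sfc = universe["signed_fold_change"].to_numpy(dtype=float)
    else:
        sfc = np.asarray(signed_fold_change(universe["log2fc"].to_numpy(dtype=float)))

    names = sorted(pathway_compounds)
    membership = np.zeros((len(names), n), dtype=bool)
    compounds = universe["compound"].to_numpy()
    for i, name in enumerate(names):
        members = pathway_compounds[name]
        membership[i] = np.isin(compounds, list(members))

    observed = membership[:, sig_mask].sum(axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names), dtype=int)
    if n > 0 and k > 0:
        for _ in range(B):
            perm = rng.choice(n, size=k, replace=False)
            hits = membership[:, perm].sum(axis=1)
            exceed += hits >= observed
    empirical = (1.0 + exceed) / (B + 1.0)

    results = []
    for i, name in enumerate(names):
        m = int(membership[i].sum())
        a = int(observed[i])
        if m == 0:
            results.append(
                PathwayResult(
                    pathway=name,
                    n_pathway_compounds_hit=0,
                    n_significant_hits=0,
                    fisher_p=1.0,
                    empirical_p=1.0,
                    direction_summary=float("nan"),
                    members=(),
                    flagged=True,
                )
            )
            continue
        table = ContingencyTable(
            sig_in=a, sig_out=k - a, nonsig_in=m - a, nonsig_out=(n - k) - (m - a)
        )
        sig_members = membership[i] & sig_mask
        direction = float(np.mean(sfc[sig_members])) if sig_members.any() else float("nan")
        fisher_p = float(stats.fisher_exact(table.as_array(), alternative="greater")[1])
        results.append(
            PathwayResult(
                pathway=name,
                n_pathway_compounds_hit=m,
                n_significant_hits=a,
                fisher_p=min(max(fisher_p, np.nextafter(0, 1)), 1.0),
                empirical_p=float(empirical[i]) if k > 0 else 1.0,
                direction_summary=direction,
                members=tuple(universe.loc[membership[i], "id"]),
            )
        )
    results.sort(key=lambda r: (r.empirical_p, r.fisher_p, r.pathway))
    return results


def results_to_frame(results) -> pd.DataFrame:
    """Tabular form of :func:`pathway_activity` output."""
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "n_pathway_compounds_hit": [r.n_pathway_compounds_hit for r in results],
            "n_significant_hits": [r.n_significant_hits for r in results],
            "fisher_p": [r.fisher_p for r in results],
            "empirical_p": [r.empirical_p for r in results],
            "direction_summary": [r.direction_summary for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
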