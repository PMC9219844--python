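"""Feature annotation: ppm-tolerance compound x adduct assignment and
co-elution grouping of multiple adducts of the same compound.

A feature is one (m/z, RT) signal.  Every (compound, adduct) pair in the
registry defines a theoretical m/z; a candidate is accepted when the signed
relative error |observed - theoretical| / theoretical is within the
tolerance (default 10 ppm).  Candidates are ranked by |ppm error|, with ties
broken by adduct priority (protonated > sodiated > ammoniated > ...) and
then compound name, so ranking is fully deterministic.  Features whose
rank-1 annotations name the same compound and elute within a short RT
window are grouped as adducts of one underlying molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Adduct, Compound, adduct_mz, ppm_error

__all__ = [
    "AnnotationCandidate",
    "AdductGroup",
    "AnnotationIndex",
    "annotate_feature",
    "annotate_table",
]

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class AnnotationCandidate:
    """One accepted (compound, adduct) identity for a feature."""

    feature_id: str
    compound: str
    adduct: str
    theoretical_mz: float
    ppm_error: float
    rank: int


@dataclass(frozen=True)
class AdductGroup:
    """Co-eluting features whose rank-1 annotation names the same compound."""

    group_id: str
    compound: str
    feature_ids: tuple
    rt_spread: float


class AnnotationIndex:
    """m/z-sorted index over all (compound, adduct) pairs of a registry.

    Queries use binary search over the sorted theoretical m/z array; the
    contract (checked by tests) is exact equality with a brute-force scan of
    every pair.
    """

    def __init__(self, registry: Sequence[Compound], adducts: Sequence[Adduct]):
        if not registry:
            raise ValueError("empty compound registry")
        if not adducts:
            raise ValueError("empty adduct set")
        entries = []
        for compound in registry:
            for priority, adduct in enumerate(adducts):
                entries.append(
                    (adduct_mz(compound.neutral_mass, adduct), compound.name, adduct.name, priority)
                )
        entries.sort(key=lambda e: e[0])
        self._mz = np.array([e[0] for e in entries])
        self._entries = entries

    def query(self, mz: float, tol_ppm: float) -> list[tuple[float, str, str, int]]:
        """All entries whose theoretical m/z is within tol_ppm of ``mz``.

        |mz - theoretical| / theoretical <= tol_ppm * 1e-6, i.e. the window in
        theoretical-mass space is [mz / (1 + tol), mz / (1 - tol)].
        """
        if tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        tol = tol_ppm * 1e-6
        lo = np.searchsorted(self._mz, mz / (1.0 + tol), side="left")
        hi = np.searchsorted(self._mz, mz / (1.0 - tol), side="right")
        return [e for e in self._entries[lo:hi] if abs(ppm_error(mz, e[0])) <= tol_ppm]


def annotate_feature(
    mz: float,
    registry: Sequence[Compound],
    adducts: Sequence[Adduct],
    tol_ppm: float = 10.0,
    feature_id: str = "",
    index: Optional[AnnotationIndex] = None,
) -> list[AnnotationCandidate]:
    """Ordered annotation candidates for one observed m/z.

    Returns every (compound, adduct) whose theoretical m/z lies within
    ``tol_ppm``, sorted by |ppm error| with ties broken by adduct priority
    and then compound name.  An empty list is a valid result.
    """
    if index is None:
        if not registry:
            return []
        index = AnnotationIndex(registry, adducts)
    hits = index.query(mz, tol_ppm)
    hits.sort(key=lambda e: (abs(ppm_error(mz, e[0])), e[3], e[1]))
    return [
        AnnotationCandidate(
            feature_id=feature_id,
            compound=name,
            adduct=adduct_name,
            theoretical_mz=theo,
            ppm_error=ppm_error(mz, theo),
            rank=rank,
        )
        for rank, (theo, name, adduct_name, _prio) in enumerate(hits, start=1)
    ]


def _group_features(
    annotated: pd.DataFrame, co_elution_window: float
) -> tuple[pd.Series, list[AdductGroup]]:
    """Single-linkage RT grouping of rank-1 co-annotated features, per compound.

    Features sorted by RT open a new group whenever the gap to the running
    group minimum exceeds the window, so each group's rt_spread stays within
    the configured co-elution window by construction.
    """
    group_ids = pd.Series("", index=annotated.index, dtype=object)
    groups: list[AdductGroup] = []
    counter = 0
    mask = annotated["compound"] != UNANNOTATED
    for compound, block in annotated[mask].groupby("compound", sort=True):
        block = block.sort_values(["rt", "id"])
        members: list[int] = []
        rt_min = None
        for idx, row in block.iterrows():
            if rt_min is not None and row["rt"] - rt_min > co_elution_window:
                counter += 1
                groups.append(_finish_group(annotated, members, compound, counter))
                for m in members:
                    group_ids.loc[m] = f"AG{counter:04d}"
                members, rt_min = [], None
            members.append(idx)
            rt_min = row["rt"] if rt_min is None else min(rt_min, row["rt"])
        if members:
            counter += 1
            groups.append(_finish_group(annotated, members, compound, counter))
            for m in members:
                group_ids.loc[m] = f"AG{counter:04d}"
    return group_ids, groups


def _finish_group(annotated, members, compound, counter) -> AdductGroup:
    rts = annotated.loc[members, "rt"]
    return AdductGroup(
        group_id=f"AG{counter:04d}",
        compound=compound,
        feature_ids=tuple(annotated.loc[members, "id"]),
        rt_spread=float(rts.max() - rts.min()),
    )


def annotate_table(
    diff_table: pd.DataFrame,
    registry: Sequence[Compound],
    adducts: Sequence[Adduct],
    tol_ppm: float = 10.0,
    co_elution_window: float = 0.2,
) -> tuple[pd.DataFrame, list[AdductGroup]]:
    """Annotate a differential feature table with rank-1 identities.

    ``diff_table`` needs columns id, mz, rt; the returned copy adds compound,
    adduct, theoretical_mz, ppm_error and adduct_group_id columns.  Features
    with no candidate carry compound="unannotated".  Features sharing a
    rank-1 compound within the co-elution window form one AdductGroup.
    """
    if diff_table.empty:
        raise ValueError("empty differential table")
    index = AnnotationIndex(registry, adducts)
    annotated = diff_table.reset_index(drop=True).copy()
    compounds, adduct_names, theo_mzs, ppms = [], [], [], []
    for _, row in annotated.iterrows():
        cands = annotate_feature(
            row["mz"], registry, adducts, tol_ppm, feature_id=row["id"], index=index
        )
        if cands:
            top = cands[0]
            compounds.append(top.compound)
            adduct_names.append(top.adduct)
            theo_mzs.append(top.theoretical_mz)
            ppms.append(top.ppm_error)
        else:
            compounds.append(UNANNOTATED)
            adduct_names.append("")
            theo_mzs.append(np.nan)
            ppms.append(np.nan)
    annotated["compound"] = compounds
    annotated["adduct"] = adduct_names
    annotated["theoretical_mz"] = theo_mzs
    annotated["ppm_error"] = ppms
    group_ids, groups = _group_features(annotated, co_elution_window)
    annotated["adduct_group_id"] = group_ids
    return annotated, groups
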