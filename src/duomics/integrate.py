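"""Dual-omics EC-set integration: the core reaction-calling procedure.

Two Enzyme Commission (EC) code sets are derived independently:

* transcript layer — significantly differentially expressed genes are
  bridged to protein domain families (PFAM accessions) and from there to
  ECs, keeping only domain-to-EC associations at or above a confidence tier
  (gold > silver > bronze);
* metabolite layer — significantly dysregulated, rank-1-annotated features
  are bridged to ECs through compound-level associations keyed by CAS
  registry number (falling back to the compound name).

The intersection of the two sets marks enzymes with dual evidence of
dysregulation.  ECs expand to reactions through an EC-to-reaction table, and
every touched reaction is classified as transcript-only, metabolite-only,
or dual ("both") evidence — the green/blue/black edge semantics of a
pathway-map overlay — and can be exported as an iPath-style selection file.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .chem import Compound

__all__ = [
    "EC_PATTERN",
    "is_valid_ec",
    "is_partial_ec",
    "TIER_RANK",
    "MappingTables",
    "ecs_from_degs",
    "ecs_from_metabolites",
    "overlap_ecs",
    "ReactionEvidence",
    "reactions_for_ecs",
    "export_ipath",
]

logger = logging.getLogger(__name__)

# four dot-separated fields; the last may be "-" for a partial classification
EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")
TIER_RANK = {"gold": 3, "silver": 2, "bronze": 1}

IPATH_COLORS = {
    "both": ("#000000", 20),
    "transcript_only": ("#00ff00", 10),
    "metabolite_only": ("#0000ff", 10),
}


def is_valid_ec(ec: str) -> bool:
    return bool(EC_PATTERN.match(ec))


def is_partial_ec(ec: str) -> bool:
    return ec.endswith(".-")


def _read_two_col(path, col_a: str, col_b: str) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (col_a, col_b):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return list(zip(df[col_a], df[col_b]))


@dataclass
class MappingTables:
    """The offline association tables bridging omics layers to reactions.

    transcript_pfam: transcript/gene id -> PFAM accessions
    pfam_ec:         PFAM -> {(EC, tier)} with tier in {gold, silver, bronze}
    compound_ec:     CAS-or-name key -> EC set
    ec_reaction:     EC -> reaction ids
    reaction_pathway: reaction id -> pathway names
    """

    transcript_pfam: dict = field(default_factory=dict)
    pfam_ec: dict = field(default_factory=dict)
    compound_ec: dict = field(default_factory=dict)
    ec_reaction: dict = field(default_factory=dict)
    reaction_pathway: dict = field(default_factory=dict)

    def validate(self) -> None:
        for pfam, links in self.pfam_ec.items():
            for ec, tier in links:
                if not is_valid_ec(ec):
                    raise ValueError(f"PFAM {pfam!r}: invalid EC {ec!r}")
                if tier not in TIER_RANK:
                    raise ValueError(f"PFAM {pfam!r}: unknown tier {tier!r}")
        for key, ecs in self.compound_ec.items():
            for ec in ecs:
                if not is_valid_ec(ec):
                    raise ValueError(f"compound key {key!r}: invalid EC {ec!r}")
        for ec in self.ec_reaction:
            if not is_valid_ec(ec):
                raise ValueError(f"reaction table: invalid EC {ec!r}")

    @classmethod
    def from_dir(cls, directory) -> "MappingTables":
        """Load the five tab-separated mapping tables from one directory.

        Expected files: transcript_pfam.tsv (transcript, pfam), pfam_ec.tsv
        (pfam, ec, tier), compound_ec.tsv (key, ec), ec_reaction.tsv
        (ec, reaction), reaction_pathway.tsv (reaction, pathway).
        """
        directory = Path(directory)
        maps = cls()
        for t, p in _read_two_col(directory / "transcript_pfam.tsv", "transcript", "pfam"):
            maps.transcript_pfam.setdefault(t, set()).add(p)
        df = pd.read_csv(directory / "pfam_ec.tsv", sep="\t", comment="#", dtype=str)
        for col in ("pfam", "ec", "tier"):
            if col not in df.columns:
                raise ValueError(f"{directory / 'pfam_ec.tsv'}: missing column {col!r}")
        for _, row in df.iterrows():
            maps.pfam_ec.setdefault(row["pfam"], set()).add((row["ec"], row["tier"]))
        for k, ec in _read_two_col(directory / "compound_ec.tsv", "key", "ec"):
            maps.compound_ec.setdefault(k, set()).add(ec)
        for ec, rxn in _read_two_col(directory / "ec_reaction.tsv", "ec", "reaction"):
            maps.ec_reaction.setdefault(ec, set()).add(rxn)
        for rxn, pw in _read_two_col(directory / "reaction_pathway.tsv", "reaction", "pathway"):
            maps.reaction_pathway.setdefault(rxn, set()).add(pw)
        maps.validate()
        return maps


def ecs_from_degs(
    degs: pd.DataFrame,
    maps: MappingTables,
    q_threshold: float = 0.05,
    tier: str = "gold",
) -> set:
    """EC set derived from the transcript layer.

    Takes the union, over genes significant at ``q_threshold``, of their
    PFAMs' EC associations at or above the requested confidence ``tier``.
    Genes with no PFAM assignment are skipped and counted in a log summary.
    """
    if tier not in TIER_RANK:
        raise ValueError(f"unknown confidence tier {tier!r}")
    min_rank = TIER_RANK[tier]
    significant = degs.loc[degs["q_value"] < q_threshold, "gene"]
    ecs: set = set()
    skipped = 0
    for gene in significant:
        pfams = maps.transcript_pfam.get(gene)
        if not pfams:
            skipped += 1
            continue
        for pfam in pfams:
            for ec, ec_tier in maps.pfam_ec.get(pfam, ()):
                if TIER_RANK[ec_tier] >= min_rank:
                    ecs.add(ec)
    if skipped:
        logger.info("ecs_from_degs: %d significant genes had no PFAM assignment", skipped)
    return ecs


def ecs_from_metabolites(
    annotated: pd.DataFrame,
    maps: MappingTables,
    registry: Optional[Sequence[Compound]] = None,
    p_threshold: float = 0.001,
) -> set:
    """EC set derived from the metabolite layer.

    Takes the union of compound-to-EC links over rank-1-annotated features
    significant at ``p_threshold`` (the stricter metabolite tier).  Lookup is
    by the compound's CAS number when a registry provides one, falling back
    to the compound name.  Unannotated features are skipped with a logged
    count.
    """
    by_name = {c.name: c for c in registry} if registry else {}
    sig = annotated[annotated["p_value"] < p_threshold]
    ecs: set = set()
    skipped = 0
    for _, row in sig.iterrows():
        compound = row.get("compound", "")
        if not compound or compound == "unannotated":
            skipped += 1
            continue
        keys = []
        comp = by_name.get(compound)
        if comp is not None and comp.cas:
            keys.append(comp.cas)
        keys.append(compound)
        for key in keys:
            links = maps.compound_ec.get(key)
            if links:
                ecs.update(links)
                break
    if skipped:
        logger.info("ecs_from_metabolites: %d significant features unannotated", skipped)
    return ecs


def overlap_ecs(transcript_ecs: Iterable[str], metabolite_ecs: Iterable[str]) -> set:
    """Exact intersection of the two layer EC sets.

    Comparison is exact string match on four-field codes; partial codes
    ("1.3.1.-") are excluded, matching nothing at overlap time.
    """
    t = {ec for ec in transcript_ecs if not is_partial_ec(ec)}
    m = {ec for ec in metabolite_ecs if not is_partial_ec(ec)}
    return t & m


@dataclass(frozen=True)
class ReactionEvidence:
    """One reaction touched by the input EC set, with its evidence class.

    ``evidence`` is "both" when the reaction's supporting ECs intersect both
    layer sets, otherwise the single layer they came from.  ``ec_evidence``
    carries the per-EC layer classification used for map export.
    """

    reaction: str
    ecs: frozenset
    evidence: str
    pathways: frozenset
    ec_evidence: tuple = ()


def reactions_for_ecs(
    ecs: Iterable[str],
    maps: MappingTables,
    layer_sets: tuple,
) -> list[ReactionEvidence]:
    """Expand an EC set to deduplicated reactions with evidence classes.

    ``layer_sets`` is (transcript EC set, metabolite EC set).  ECs absent
    from the reaction table are logged and skipped.  One record is returned
    per distinct reaction, sorted by reaction id.
    """
    transcript_set, metabolite_set = (set(layer_sets[0]), set(layer_sets[1]))
    per_reaction: dict[str, set] = {}
    missing = 0
    for ec in sorted(set(ecs)):
        reactions = maps.ec_reaction.get(ec)
        if not reactions:
            missing += 1
            continue
        for rxn in reactions:
            per_reaction.setdefault(rxn, set()).add(ec)
    if missing:
        logger.info("reactions_for_ecs: %d ECs absent from the reaction table", missing)

    def ec_class(ec: str) -> str:
        in_t, in_m = ec in transcript_set, ec in metabolite_set
        if in_t and in_m:
            return "both"
        return "transcript_only" if in_t else "metabolite_only"

    records = []
    for rxn in sorted(per_reaction):
        supp = per_reaction[rxn]
        in_t = bool(supp & transcript_set)
        in_m = bool(supp & metabolite_set)
        if in_t and in_m:
            evidence = "both"
        elif in_t:
            evidence = "transcript_only"
        else:
            evidence = "metabolite_only"
        records.append(
            ReactionEvidence(
                reaction=rxn,
                ecs=frozenset(supp),
                evidence=evidence,
                pathways=frozenset(maps.reaction_pathway.get(rxn, ())),
                ec_evidence=tuple((ec, ec_class(ec)) for ec in sorted(supp)),
            )
        )
    return records


def export_ipath(records: Sequence[ReactionEvidence], path) -> None:
    """Write an iPath-style selection file from reaction evidence records.

    One line per EC: "<EC> <hexcolor> W<width>".  ECs present in both layers
    are bold black (W20); transcript-only evidence is green, metabolite-only
    blue (both W10).  Lines are sorted by EC string for stable output.
    """
    if not records:
        raise ValueError("no reaction evidence records to export")
    ec_class: dict[str, str] = {}
    for rec in records:
        for ec, cls in rec.ec_evidence:
            # "both" dominates if the same EC appears under several records
            if ec_class.get(ec) != "both":
                ec_class[ec] = cls
    lines = []
    for ec in sorted(ec_class):
        color, width = IPATH_COLORS[ec_class[ec]]
        lines.append(f"{ec} {color} W{width}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
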