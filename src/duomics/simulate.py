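"""Synthetic paired-omics data with planted ground truth.

The generator emulates a two-group (vehicle control vs treated) cell-culture
experiment with three biological replicates per group in each omics layer:

* metabolomics — each simulated compound is emitted as 1-3 co-eluting adduct
  features (primary protonated form plus optional sodiated / potassiated /
  water-loss forms at fixed relative abundances).  Feature m/z is the exact
  theoretical adduct m/z plus a truncated Gaussian mass error in ppm;
  retention times follow a two-cluster (hydrophilic < 5 min, hydrophobic
  >= 5 min) elution model, and every sample run receives a smooth linear RT
  warp (slope ~ N(1, 0.01), offset ~ N(0, rt shift sd)) to exercise the
  alignment stage.  Intensities are log-normal; a planted fraction of
  compounds carries a true multiplicative fold-change between groups.

* transcriptomics — gene counts are negative-binomial around size-scaled
  log-uniform means; a planted fraction of adequately expressed genes
  carries a true log2 fold-change.

* mapping layer — genes link to PFAM domain accessions, PFAMs to EC codes
  with confidence tiers, compounds to ECs, ECs to reactions and reactions to
  pathways, all drawn from one EC universe.  A fraction of planted
  differential compounds is deliberately wired to planted DE genes through a
  shared EC, so the true dual-evidence (overlap) EC set is non-trivial; the
  recorded truth is always the exact intersection of the two per-layer true
  EC sets, wired or incidental.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import (
    Adduct,
    Compound,
    adduct_mz,
    default_adducts,
    load_adducts,
    load_compounds,
    monoisotopic_mass,
    parse_formula,
    write_adducts,
    write_compounds,
)
from .integrate import MappingTables
from .metabolomics import FeatureTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "make_registry",
    "simulate",
    "write_fixture",
    "read_fixture",
    "datasets_equal",
]

SECONDARY_ADDUCTS = ("M+Na[1+]", "M+K[1+]", "M-H2O[1+]")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dual-omics experiment.

    Defaults mirror the emulated design: 3 vs 3 biological replicates,
    100 compounds of which 20% are differential with 4-32x fold-changes and
    log-normal intensity noise (sd 0.3 in log2 units), and 1000 genes of
    which 10% are differential at negative-binomial dispersion 0.05.
    """

    n_control: int = 3
    n_treated: int = 3
    # metabolomics layer
    n_compounds: int = 100
    frac_differential: float = 0.2
    fold_change_range: tuple = (4.0, 32.0)
    intensity_log_sd: float = 0.3  # sd of log2 intensity noise
    base_intensity_range: tuple = (1e4, 1e7)
    adduct_rel_abundance: tuple = (1.0, 0.3, 0.1)
    adduct_count_probs: tuple = (0.1, 0.3, 0.6)  # P(1), P(2), P(3) adducts per compound
    mz_ppm_sd: float = 2.0  # Gaussian mass error, ppm
    mz_ppm_max: float = 5.0  # truncation bound, ppm
    rt_hydrophilic: tuple = (1.5, 0.8)  # mean, sd (minutes); elutes < 5 min
    rt_hydrophobic: tuple = (8.5, 1.8)  # elutes >= 5 min
    frac_hydrophobic: float = 0.4
    per_sample_rt_shift_sd: float = 0.05  # minutes
    rt_slope_sd: float = 0.01
    # transcript layer
    n_genes: int = 1000
    frac_de_genes: float = 0.1
    nb_dispersion: float = 0.05
    mean_count_range: tuple = (2.0, 2000.0)
    de_mean_floor: float = 50.0  # planted DE genes drawn from genes this expressed
    gene_log2fc_range: tuple = (2.0, 6.0)
    # mapping layer
    n_ecs: int = 300
    n_pfams: int = 400
    n_pathways: int = 12
    p_link_overlap: float = 0.6  # prob a diff compound shares an EC with a DE gene
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_control, self.n_treated, self.n_compounds, self.n_genes) < 1:
            raise ValueError("all design counts must be >= 1")
        for frac in (self.frac_differential, self.frac_de_genes):
            if not 0 < frac < 1:
                raise ValueError("fractions must lie in (0, 1)")
        lo, hi = self.fold_change_range
        if lo <= 1 or hi < lo:
            raise ValueError("fold-change range must satisfy 1 < low <= high")
        if self.intensity_log_sd < 0 or self.nb_dispersion < 0:
            raise ValueError("noise parameters must be non-negative")
        if round(self.n_compounds * self.frac_differential) < 1:
            raise ValueError("configuration plants zero differential compounds")
        if round(self.n_genes * self.frac_de_genes) < 1:
            raise ValueError("configuration plants zero DE genes")


@dataclass
class GroundTruth:
    """Planted truth recorded alongside the synthetic dataset.

    ``differential_compounds`` maps compound name to the true signed display
    fold-change; ``de_genes`` maps gene id to true log2 fold-change.  The EC
    sets are the per-layer truths, and ``overlap`` their exact intersection.
    ``feature_truth`` maps feature id to its generating (compound, adduct,
    theoretical m/z, relative abundance).
    """

    differential_compounds: dict = field(default_factory=dict)
    de_genes: dict = field(default_factory=dict)
    transcript_ecs: set = field(default_factory=set)
    metabolite_ecs: set = field(default_factory=set)
    overlap_ecs: set = field(default_factory=set)
    feature_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.overlap_ecs != self.transcript_ecs & self.metabolite_ecs:
            raise ValueError("true overlap must equal the intersection of the layer truths")

    def to_json(self) -> dict:
        return {
            "differential_compounds": self.differential_compounds,
            "de_genes": self.de_genes,
            "transcript_ecs": sorted(self.transcript_ecs),
            "metabolite_ecs": sorted(self.metabolite_ecs),
            "overlap_ecs": sorted(self.overlap_ecs),
            "feature_truth": self.feature_truth,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        return cls(
            differential_compounds=dict(obj["differential_compounds"]),
            de_genes=dict(obj["de_genes"]),
            transcript_ecs=set(obj["transcript_ecs"]),
            metabolite_ecs=set(obj["metabolite_ecs"]),
            overlap_ecs=set(obj["overlap_ecs"]),
            feature_truth={k: dict(v) for k, v in obj["feature_truth"].items()},
        )


@dataclass
class SyntheticDataset:
    """A complete simulated experiment plus its mapping tables and truth."""

    config: SimulationConfig
    registry: list
    adducts: list
    feature_table: FeatureTable  # merged, true (unwarped) retention times
    runs: list  # [(sample, DataFrame[id, mz, rt, intensity])] with warped RT
    counts: pd.DataFrame  # gene x sample
    rna_sample_groups: dict
    maps: MappingTables
    pathway_compounds: dict
    truth: GroundTruth


def _unique_ecs(rng: np.random.Generator, n: int) -> list[str]:
    ecs: set = set()
    while len(ecs) < n:
        ecs.add(
            f"{rng.integers(1, 8)}.{rng.integers(1, 21)}.{rng.integers(1, 31)}."
            f"{rng.integers(1, 400)}"
        )
    return sorted(ecs)


def _random_formula(rng: np.random.Generator) -> dict:
    c = int(rng.integers(5, 41))
    h = int(rng.integers(c, 2 * c + 3))
    n = int(rng.integers(0, 5))
    o = int(rng.integers(0, 9))
    formula = {"C": c, "H": h}
    if n:
        formula["N"] = n
    if o:
        formula["O"] = o
    return formula


def make_registry(
    n_compounds: int,
    rng: np.random.Generator,
    ec_universe: Sequence[str],
    pathways: Sequence[str],
) -> list[Compound]:
    """Generate a synthetic compound registry with well-separated masses.

    Compound masses are kept >= 20 ppm apart so annotation has a unique true
    answer for every planted feature; each compound carries 1-2 EC links and
    one pathway assignment, plus a synthetic CAS-format identifier.
    """
    compounds = []
    masses: list[float] = []
    for i in range(n_compounds):
        for _ in range(1000):
            formula = _random_formula(rng)
            mass = monoisotopic_mass(formula)
            if not 80.0 < mass < 950.0:
                continue
            if masses and min(abs(mass - m) / m for m in masses) * 1e6 < 20.0:
                continue
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not place a well-separated compound mass")
        masses.append(mass)
        n_ec = int(rng.integers(1, 3))
        ec_links = frozenset(rng.choice(ec_universe, size=n_ec, replace=False).tolist())
        pathway = str(rng.choice(pathways))
        cas = f"{rng.integers(10000, 999999)}-{rng.integers(10, 99)}-{rng.integers(0, 9)}"
        compounds.append(
            Compound(
                name=f"SYN{i + 1:04d}",
                formula=formula,
                neutral_mass=mass,
                cas=cas,
                kegg=None,
                ec_links=ec_links,
                pathways=frozenset({pathway}),
                verified=True,
            )
        )
    return compounds


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate(config: SimulationConfig, registry: Optional[Sequence[Compound]] = None) -> SyntheticDataset:
    """Run the generator; reproducible given ``config.seed``.

    If ``registry`` is supplied it must contain at least ``n_compounds``
    compounds (the first ``n_compounds`` are used); otherwise a synthetic
    registry is generated.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    pathways = [f"pathway_{i + 1:02d}" for i in range(config.n_pathways)]
    ec_universe = _unique_ecs(rng, config.n_ecs)

    if registry is None:
        registry = make_registry(config.n_compounds, rng, ec_universe, pathways)
    else:
        if len(registry) < config.n_compounds:
            raise ValueError(
                f"registry has {len(registry)} compounds; config needs {config.n_compounds}"
            )
        registry = list(registry)[: config.n_compounds]
        ec_universe = sorted(set(ec_universe) | {ec for c in registry for ec in c.ec_links})

    # --- choose planted differential compounds (clustered into 3 pathways) ---
    n_diff = int(round(config.n_compounds * config.frac_differential))
    perturbed = set(
        rng.choice(pathways, size=min(3, len(pathways)), replace=False).tolist()
    )
    weights = np.array(
        [4.0 if (c.pathways & perturbed) else 1.0 for c in registry], dtype=float
    )
    weights /= weights.sum()
    diff_idx = rng.choice(len(registry), size=n_diff, replace=False, p=weights)
    diff_mask = np.zeros(len(registry), dtype=bool)
    diff_mask[diff_idx] = True

    lo, hi = config.fold_change_range
    folds = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_diff))
    up = rng.random(n_diff) < 0.5
    ratio_by_idx = {}
    signed_by_name = {}
    for j, idx in enumerate(diff_idx):
        ratio = folds[j] if up[j] else 1.0 / folds[j]
        ratio_by_idx[int(idx)] = ratio
        signed_by_name[registry[idx].name] = float(folds[j] if up[j] else -folds[j])

    # --- features: 1-3 adducts per compound ---
    adducts = {a.name: a for a in default_adducts()}
    feature_rows = []
    feature_truth = {}
    for i, compound in enumerate(registry):
        n_add = int(rng.choice([1, 2, 3], p=config.adduct_count_probs))
        names = ["M+H[1+]"] + [
            str(x) for x in rng.choice(SECONDARY_ADDUCTS, size=n_add - 1, replace=False)
        ]
        hydrophobic = rng.random() < config.frac_hydrophobic
        mu, sd = config.rt_hydrophobic if hydrophobic else config.rt_hydrophilic
        rt_base = float(np.clip(rng.normal(mu, sd), 5.0 if hydrophobic else 0.2, 13.5))
        if not hydrophobic:
            rt_base = min(rt_base, 4.9)
        base_intensity = float(
            np.exp(
                rng.uniform(
                    np.log(config.base_intensity_range[0]),
                    np.log(config.base_intensity_range[1]),
                )
            )
        )
        for k, adduct_name in enumerate(names):
            adduct = adducts[adduct_name]
            theo = adduct_mz(compound.neutral_mass, adduct)
            ppm = float(
                np.clip(rng.normal(0.0, config.mz_ppm_sd), -config.mz_ppm_max, config.mz_ppm_max)
            )
            obs_mz = theo * (1.0 + ppm * 1e-6)
            rt = float(np.clip(rt_base + rng.normal(0.0, 0.01), 0.05, 14.0))
            rel = config.adduct_rel_abundance[min(k, len(config.adduct_rel_abundance) - 1)]
            fid = f"F{i + 1:04d}A{k + 1}"
            feature_rows.append(
                {
                    "id": fid,
                    "mz": obs_mz,
                    "rt": rt,
                    "compound_idx": i,
                    "mean": base_intensity * rel,
                }
            )
            feature_truth[fid] = {
                "compound": compound.name,
                "adduct": adduct_name,
                "theoretical_mz": theo,
                "rel_abundance": rel,
            }

    samples = [f"ctrl_{j + 1}" for j in range(config.n_control)] + [
        f"trt_{j + 1}" for j in range(config.n_treated)
    ]
    sample_groups = {
        s: ("control" if s.startswith("ctrl") else "treated") for s in samples
    }

    features = pd.DataFrame(feature_rows)
    intensities = np.empty((len(features), len(samples)))
    means = features["mean"].to_numpy()
    comp_idx = features["compound_idx"].to_numpy()
    for j, sample in enumerate(samples):
        treated = sample_groups[sample] == "treated"
        mult = np.array(
            [ratio_by_idx.get(int(ci), 1.0) if treated else 1.0 for ci in comp_idx]
        )
        noise = np.exp2(rng.normal(0.0, config.intensity_log_sd, size=len(features)))
        intensities[:, j] = means * mult * noise

    table_df = features[["id", "mz", "rt"]].copy()
    for j, sample in enumerate(samples):
        table_df[sample] = intensities[:, j]
    feature_table = FeatureTable(data=table_df, sample_groups=sample_groups)

    # --- per-sample runs with smooth linear RT warps ---
    runs = []
    for j, sample in enumerate(samples):
        slope = float(rng.normal(1.0, config.rt_slope_sd))
        offset = float(rng.normal(0.0, config.per_sample_rt_shift_sd))
        run_df = pd.DataFrame(
            {
                "id": features["id"],
                "mz": features["mz"],
                "rt": np.clip(slope * features["rt"].to_numpy() + offset, 0.01, None),
                "intensity": intensities[:, j],
            }
        )
        runs.append((sample, run_df))

    # --- transcript layer ---
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    gene_means = np.exp(
        rng.uniform(
            np.log(config.mean_count_range[0]),
            np.log(config.mean_count_range[1]),
            size=config.n_genes,
        )
    )
    n_de = int(round(config.n_genes * config.frac_de_genes))
    eligible = np.flatnonzero(gene_means >= config.de_mean_floor)
    if len(eligible) < n_de:
        raise ValueError(
            f"only {len(eligible)} genes pass the DE expression floor; need {n_de}"
        )
    de_idx = rng.choice(eligible, size=n_de, replace=False)
    gene_l2fc = np.zeros(config.n_genes)
    mag = rng.uniform(*config.gene_log2fc_range, size=n_de)
    sign = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
    gene_l2fc[de_idx] = mag * sign

    rna_samples = [f"rna_ctrl_{j + 1}" for j in range(config.n_control)] + [
        f"rna_trt_{j + 1}" for j in range(config.n_treated)
    ]
    rna_groups = {
        s: ("control" if "ctrl" in s else "treated") for s in rna_samples
    }
    depths = rng.uniform(0.7, 1.4, size=len(rna_samples))
    count_cols = {}
    for j, sample in enumerate(rna_samples):
        mu = gene_means * depths[j]
        if rna_groups[sample] == "treated":
            mu = mu * np.exp2(gene_l2fc)
        count_cols[sample] = _nb_draw(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(count_cols, index=pd.Index(genes, name="gene"))

    # --- mapping tables ---
    pfams = [f"PF{i + 1:05d}" for i in range(config.n_pfams)]
    gene_pfam = {g: {str(rng.choice(pfams))} for g in genes}
    pfam_ec: dict = {}
    for pfam in pfams:
        n_ec = int(rng.integers(1, 3))
        links = {(str(ec), "gold") for ec in rng.choice(ec_universe, size=n_ec, replace=False)}
        if rng.random() < 0.10:
            links.add((str(rng.choice(ec_universe)), "silver"))
        if rng.random() < 0.05:
            links.add((str(rng.choice(ec_universe)), "bronze"))
        pfam_ec[pfam] = links

    de_genes = [genes[i] for i in de_idx]
    # dual-evidence wiring: a linked compound's EC is modeled as catalyzed by a
    # small isozyme family, i.e. the PFAMs of two planted DE transcripts
    for idx in diff_idx:
        compound = registry[idx]
        if rng.random() < config.p_link_overlap and compound.ec_links:
            n_iso = min(2, len(de_genes))
            target_genes = rng.choice(de_genes, size=n_iso, replace=False)
            shared_ec = str(rng.choice(sorted(compound.ec_links)))
            for target_gene in target_genes:
                pfam = next(iter(gene_pfam[str(target_gene)]))
                pfam_ec[pfam].add((shared_ec, "gold"))

    compound_ec = {
        (c.cas or c.name): set(c.ec_links) for c in registry if c.ec_links
    }
    ec_reaction: dict = {}
    reaction_pathway: dict = {}
    rxn_counter = 0
    for ec in ec_universe:
        n_rxn = int(rng.integers(1, 3))
        for _ in range(n_rxn):
            rxn_counter += 1
            rxn = f"R{rxn_counter:05d}"
            ec_reaction.setdefault(ec, set()).add(rxn)
            reaction_pathway[rxn] = {str(rng.choice(pathways))}
    maps = MappingTables(
        transcript_pfam=gene_pfam,
        pfam_ec=pfam_ec,
        compound_ec=compound_ec,
        ec_reaction=ec_reaction,
        reaction_pathway=reaction_pathway,
    )
    maps.validate()

    pathway_compounds: dict = {p: set() for p in pathways}
    for c in registry:
        for p in c.pathways:
            pathway_compounds.setdefault(p, set()).add(c.name)

    true_transcript = set()
    for g in de_genes:
        for pfam in gene_pfam[g]:
            true_transcript.update(ec for ec, tier in pfam_ec[pfam] if tier == "gold")
    true_metabolite = set()
    for idx in diff_idx:
        true_metabolite.update(registry[idx].ec_links)

    for fid, info in feature_truth.items():
        info["true_signed_fold"] = signed_by_name.get(info["compound"], 1.0)

    truth = GroundTruth(
        differential_compounds=signed_by_name,
        de_genes={genes[i]: float(gene_l2fc[i]) for i in de_idx},
        transcript_ecs=true_transcript,
        metabolite_ecs=true_metabolite,
        overlap_ecs=true_transcript & true_metabolite,
        feature_truth=feature_truth,
    )

    return SyntheticDataset(
        config=config,
        registry=list(registry),
        adducts=list(adducts.values()),
        feature_table=feature_table,
        runs=runs,
        counts=counts,
        rna_sample_groups=rna_groups,
        maps=maps,
        pathway_compounds=pathway_compounds,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture round-trip
# ---------------------------------------------------------------------------


def _write_pairs(path, header: Sequence[str], rows) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_fixture(dataset: SyntheticDataset, directory) -> list[Path]:
    """Write the dataset as the pipeline's delimited input formats.

    Returns the list of written paths.  A read via :func:`read_fixture`
    reconstructs an equal dataset.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "runs").mkdir(exist_ok=True)
    paths: list[Path] = []

    def reg(p: Path) -> Path:
        paths.append(p)
        return p

    write_compounds(dataset.registry, reg(directory / "compounds.tsv"))
    write_adducts(dataset.adducts, reg(directory / "adducts.tsv"))
    dataset.feature_table.to_tsv(
        reg(directory / "features.tsv"), reg(directory / "samples_metabolomics.tsv")
    )
    for sample, df in dataset.runs:
        df.to_csv(reg(directory / "runs" / f"{sample}.tsv"), sep="\t", index=False)
    dataset.counts.to_csv(reg(directory / "counts.tsv"), sep="\t")
    _write_pairs(
        reg(directory / "samples_rnaseq.tsv"),
        ["sample", "group"],
        sorted(dataset.rna_sample_groups.items()),
    )
    maps = dataset.maps
    _write_pairs(
        reg(directory / "transcript_pfam.tsv"),
        ["transcript", "pfam"],
        sorted((t, p) for t, ps in maps.transcript_pfam.items() for p in ps),
    )
    _write_pairs(
        reg(directory / "pfam_ec.tsv"),
        ["pfam", "ec", "tier"],
        sorted((pf, ec, tier) for pf, links in maps.pfam_ec.items() for ec, tier in links),
    )
    _write_pairs(
        reg(directory / "compound_ec.tsv"),
        ["key", "ec"],
        sorted((k, ec) for k, ecs in maps.compound_ec.items() for ec in ecs),
    )
    _write_pairs(
        reg(directory / "ec_reaction.tsv"),
        ["ec", "reaction"],
        sorted((ec, r) for ec, rs in maps.ec_reaction.items() for r in rs),
    )
    _write_pairs(
        reg(directory / "reaction_pathway.tsv"),
        ["reaction", "pathway"],
        sorted((r, p) for r, ps in maps.reaction_pathway.items() for p in ps),
    )
    _write_pairs(
        reg(directory / "pathway_compounds.tsv"),
        ["pathway", "compound"],
        sorted((p, c) for p, cs in dataset.pathway_compounds.items() for c in cs),
    )
    payload = {
        "config": asdict(dataset.config),
        "truth": dataset.truth.to_json(),
    }
    reg(directory / "truth.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8"
    )
    return paths


def read_fixture(directory) -> SyntheticDataset:
    """Reconstruct a :class:`SyntheticDataset` written by :func:`write_fixture`."""
    directory = Path(directory)
    payload = json.loads((directory / "truth.json").read_text(encoding="utf-8"))
    cfg_dict = payload["config"]
    for key in ("fold_change_range", "base_intensity_range", "adduct_rel_abundance",
                "adduct_count_probs", "rt_hydrophilic", "rt_hydrophobic",
                "mean_count_range", "gene_log2fc_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = SimulationConfig(**cfg_dict)
    registry = load_compounds(directory / "compounds.tsv")
    adducts = load_adducts(directory / "adducts.tsv")
    feature_table = FeatureTable.from_tsv(
        directory / "features.tsv", directory / "samples_metabolomics.tsv"
    )
    runs = []
    for sample in feature_table.samples:
        runs.append(
            (sample, pd.read_csv(directory / "runs" / f"{sample}.tsv", sep="\t"))
        )
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col="gene")
    rna_sheet = pd.read_csv(directory / "samples_rnaseq.tsv", sep="\t")
    rna_groups = dict(zip(rna_sheet["sample"], rna_sheet["group"]))
    maps = MappingTables.from_dir(directory)
    pw = pd.read_csv(directory / "pathway_compounds.tsv", sep="\t")
    pathway_compounds: dict = {}
    for _, row in pw.iterrows():
        pathway_compounds.setdefault(row["pathway"], set()).add(row["compound"])
    truth = GroundTruth.from_json(payload["truth"])
    return SyntheticDataset(
        config=config,
        registry=registry,
        adducts=adducts,
        feature_table=feature_table,
        runs=runs,
        counts=counts,
        rna_sample_groups=rna_groups,
        maps=maps,
        pathway_compounds=pathway_compounds,
        truth=truth,
    )


def datasets_equal(a: SyntheticDataset, b: SyntheticDataset, rtol: float = 1e-9) -> bool:
    """Numerical equality of two datasets (frames to rtol, mappings exactly)."""
    if a.config != b.config:
        return False
    ta, tb = a.feature_table.data, b.feature_table.data
    if list(ta.columns) != list(tb.columns) or len(ta) != len(tb):
        return False
    for col in ta.columns:
        if ta[col].dtype.kind in "fc":
            if not np.allclose(ta[col], tb[col], rtol=rtol):
                return False
        elif not (ta[col] == tb[col]).all():
            return False
    if not a.counts.equals(b.counts):
        return False
    if a.maps.pfam_ec != b.maps.pfam_ec or a.maps.transcript_pfam != b.maps.transcript_pfam:
        return False
    if a.truth.to_json() != b.truth.to_json():
        return False
    return True
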