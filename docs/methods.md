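# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `duomics`. It is written for a reader who wants to
know exactly what each stage computes and what the synthetic benchmark does
and does not demonstrate.

## 1. Mass arithmetic and annotation

**Monoisotopic mass.** A molecular formula parsed from Hill notation is
summed over IUPAC monoisotopic atomic masses (carbon exactly 12 u by
definition). The element table covers the biologically common elements
(H, C, N, O, Na, Mg, P, S, Cl, K, Ca, F, Fe, Cu, Zn, Se, Br, I) to at least
six decimals, which is required for parts-per-million work: a 1 mu error on
a 200 Da ion is already 5 ppm.

**Adducts.** Positive-mode ionized forms are modeled as
m/z = (M + Δ) / z with electron-corrected shifts Δ:

| adduct | Δ (u) | z |
|---|---|---|
| M+H[1+] | +1.007276 | 1 |
| M+Na[1+] | +22.989218 | 1 |
| M+NH3[1+] (ammonium) | +18.033823 | 1 |
| M+K[1+] | +38.963158 | 1 |
| M−H2O[1+] | −17.003289 | 1 |
| M−NH3[1+] | −16.019274 | 1 |
| M+2H[2+] | +2.014552 | 2 |
| M+H+Na[2+] | +23.996494 | 2 |

These are the standard definitions (the added hydrogen is a proton, not a
hydrogen atom). The inverse map `neutral_mass_from_mz` is exact to 1e-9 u.

**Registry fixture.** The packaged compound registry carries the named
metabolites of the study's upregulated (pellet) and downregulated
(conditioned media) tables with curated formulas, CAS/KEGG identifiers
where confidently known, EC links, and pathway labels. Each observed
(compound, adduct, m/z) row in the companion fixture is flagged
`verified=true` only when the printed m/z is within 10 ppm of theory under
the adduct definitions above; seven printed rows fail this check by 2000+
ppm (internally inconsistent assignments, e.g. a "glutathione disulfide
M+2H" feature whose m/z is actually protonated reduced glutathione) and are
retained but flagged `false`. No attempt is made to guess what produced
those rows.

**Annotation.** A feature at observed m/z receives every (compound, adduct)
whose theoretical m/z satisfies |obs − theo|/theo ≤ 10 ppm (configurable).
Matching runs on an m/z-sorted index with binary search; the test suite
holds it exactly equal to a brute-force scan of all pairs. Candidates are
ranked by |ppm error|, ties broken by adduct priority
(M+H > M+Na > M+NH4 > M+K > M−H2O > M−NH3 > doubly charged — typical
positive-ESI abundance order) and then compound name, so ranking is fully
deterministic. Features whose rank-1 annotations share a compound within a
0.2 min co-elution window (single-linkage on RT) form one adduct group.
Isomers are not disambiguated: distinct compounds with equal formula (e.g.
resolvin E1 and 5S-hydroperoxy-18R-hydroxy-eicosapentaenoate) are both
reported as candidates and the tie-break decides display order.

## 2. Retention-time alignment

Features are matched across runs by m/z gap clustering (consecutive sorted
m/z within the ppm tolerance join a cluster). Clusters represented exactly
once in at least `anchor_min_presence` of the runs are anchors — the "peak
groups present in most/all samples" idea. The run whose anchor RTs are
closest (mean absolute deviation) to the cross-run anchor medians is the
reference; every run gets a piecewise-linear map from its anchor RTs onto
the reference anchor RTs, forced monotone by a cumulative-maximum pass, with
slope-1 (edge-offset) extrapolation outside the anchor range so the map is
continuous. Mapping onto a concrete reference run rather than onto the
pointwise median makes a constant inter-run offset collapse exactly to the
reference chromatogram, which is the verifiable contract the tests use.
Merged consensus features take the median corrected RT and median m/z of
their cluster members.

## 3. Differential statistics

**Metabolite features.** Intensities are modeled log-normal. The test is a
Welch (unequal-variance) two-sided t on log2(I + c) with pseudo-intensity
c = 1.0 guarding zeros, which occur routinely in MS intensity matrices.
Degenerate cases are fixed by convention: both groups constant and equal →
p = 1; constant but unequal → p = 0; fewer than two values in a group →
p = NaN (flagged), with the fold-change still reported. Two significance
tiers are carried through the pipeline: q < 0.05 (BH-FDR, the default
reporting tier) and raw p < 0.001 (the stricter tier used for the
metabolite→EC step and enrichment).

**Genes.** The DE stage is deliberately NOT a negative-binomial GLM engine.
Counts are normalized by median-of-ratios size factors (the ratio of each
sample's counts to gene-wise geometric means, median over genes expressed in
all samples), then the same Welch-on-log2(x+1) machinery and BH adjustment
are applied. This stand-in is validated only against planted synthetic
truth (sensitivity ≥ 0.8 for |log2FC| ≥ 2 at n = 3/3, dispersion 0.05;
pooled empirical FDR ≤ 0.08 over 200 simulations); per-gene agreement with
any specific published DE engine is out of scope, because the package's
contribution is the downstream integration, not the DE engine.

**Fold-change display.** With r = 2^{log2FC}, increases print as +r and
decreases as −1/r, so a 5-fold drop is −5 and |signed fold| ≥ 1 always.
With the pseudo-count, a zero-noise dataset recovers planted fold-changes
up to a relative bias bounded by c/min(I); at the simulated intensity floor
of 1e4 this is < 1e-3, and tests assert recovery at that tolerance.

## 4. EC-set integration

The transcript layer takes genes at q < 0.05, follows the
transcript → PFAM → EC tables, and keeps domain-to-EC associations at or
above the requested confidence tier (gold > silver > bronze; default gold).
The metabolite layer takes rank-1-annotated features at p < 0.001 and
follows compound → EC links keyed by CAS registry number, falling back to
the compound name. The dual-evidence set is the exact string intersection
of four-field EC codes; partial codes ("1.3.1.-") are syntactically
accepted but match nothing at overlap time, since no principled partial-match
rule exists. ECs expand to reactions through the EC → reaction table; a
reaction's evidence class is "both" when its supporting ECs intersect both
layer sets, else the single layer seen. The iPath-style export writes one
line per EC — `<EC> <hexcolor> W<width>` — black/W20 for dual evidence,
green/W10 transcript-only, blue/W10 metabolite-only.

## 5. Pathway activity

The enrichment universe is the annotated features (those with a rank-1
compound), conditioning on annotatable mass space as Mummichog-style
methods do, rather than all detected features. Per pathway, the 2×2 table
(significant × member) is scored with a one-sided (enrichment) Fisher exact
test, and with an empirical permutation p: B = 999 random "significant"
sets of the observed size are resampled from the universe (feature ids,
preserving annotation structure) and
p = (1 + #{permuted hits ≥ observed}) / (B + 1), never exactly zero. The
one-sided Fisher is used here because the permutation null is
enrichment-directed; the two ways of scoring then agree in rank (Spearman
≥ 0.9 on synthetic data). A standalone two-sided Fisher primitive is also
exposed and is held equal to a full hypergeometric enumeration in tests.
Pathway direction is the mean signed fold-change of the significant member
features — positive means the pathway's metabolites accumulate under
treatment. Pathways with no annotated member are reported flagged with
p = 1 rather than dropped.

## 6. The synthetic benchmark

The generator emulates the study design: two groups × three biological
replicates in each omics layer.

Metabolomics: 100 compounds (default) with masses kept ≥ 20 ppm apart;
20% planted differential with multiplicative fold-changes log-uniform in
[4, 32], direction random; intensities log-normal with sd 0.3 in log2
units around compound base abundances log-uniform in [1e4, 1e7]. Each
compound emits its protonated ion plus secondary adducts at relative
abundances 1.0/0.3/0.1, with multiplicity probabilities
P(1, 2, 3 adducts) = (0.1, 0.3, 0.6) — most small metabolites in
positive-mode ESI show a cationized or in-source-loss form next to M+H,
and this multiplicity is what makes adduct grouping and the strict
metabolite tier workable at n = 3. Feature m/z carries Gaussian mass error
(sd 2 ppm, truncated at 5 ppm = half the matching tolerance); retention
times follow a two-cluster elution model (hydrophilic N(1.5, 0.8) min
clipped below 5; hydrophobic N(8.5, 1.8) clipped to ≥ 5), and every sample
run is warped by rt → a·rt + b with a ~ N(1, 0.01), b ~ N(0, 0.05 min) to
exercise alignment.

Transcriptomics: 1000 genes with means log-uniform in [2, 2000], sample
depth factors uniform in [0.7, 1.4], counts negative-binomial with
var = μ + 0.05 μ². 10% of genes are planted DE with |log2FC| uniform in
[2, 6], drawn from genes with base mean ≥ 50 — differential calling at
n = 3 requires detectable expression, and planting below that floor would
only measure the floor, not the integration.

Mappings: one EC universe of 300 codes; each compound links 1–2 ECs, each
of 400 PFAMs 1–2 gold ECs (plus occasional silver/bronze links to exercise
tier filtering), each gene one PFAM, each EC 1–2 reactions, each reaction
one of 12 pathways. For 60% of planted differential compounds, one of the
compound's ECs is additionally wired into the PFAMs of two planted DE
transcripts — modeling an enzyme encoded by a small isozyme family — which
makes the planted dual-evidence set recoverable rather than borderline at
the strict significance tiers. The recorded true overlap is always the
exact intersection of the two per-layer truths, wired or incidental.

**What passing the benchmark shows, and what it does not.** The benchmark
demonstrates that the pipeline's statistics are calibrated (FDR control,
uniform permutation null), that its exact primitives match independent
oracles, and that the integration recovers a planted dual-evidence reaction
set (mean Jaccard ≈ 0.79 against truth over 50 seeds at defaults). It does
not demonstrate performance on real LC–MS data: the generator has no
isotope patterns, in-source fragments beyond the fixed neutral losses,
batch effects, missing-value structure, heteroscedastic low-intensity
noise, or correlated gene expression, and real compound databases have far
denser mass space (more annotation ambiguity) than 100 well-separated
synthetic masses.

## 7. Problem sizes and determinism

Default analysis scales (100 compounds ≈ 250 features, 1000 genes, B = 999
permutations) run in under a second per dataset; the repeated-simulation
validations use 200 datasets for FDR pooling, 50 seeds for integration
recovery, and 500 null draws at B = 199 for calibration. All randomness —
generator, permutations — flows from a single integer seed; two runs with
the same configuration produce byte-identical tabular outputs, and every
output table records the seed in a header comment.
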