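# Methods

`evfrac` re-implements, as a tested library, a meta-analysis strategy for
extracellular-vesicle (EV) proteomics: classify published proteomic datasets
into small-EV (sEV, exosome-enriched) and large-EV (lEV, ectosome-enriched)
fractions from their purification protocols, and then ask how the two
fractions differ in protein identification frequency, evolutionary
conservation, interaction-network topology and functional enrichment.

## Dataset classification from DUC protocols

Differential ultracentrifugation (DUC) protocols are consumed as structured
metadata: an ordered list of spins, each with a relative centrifugal force in
x g and a role (`PRECLEAR` or the single retained `PELLET`). With `P` the
pellet speed and `C` the maximum pre-clearance speed (0 if none):

* **sEV** iff `P >= 100,000 x g` and `C >= 10,000 x g`;
* **lEV** iff `P <= 20,000 x g` and `C < 10,000 x g`;
* otherwise **excluded**, with a reason (no adequate pre-clearance for a
  high-speed pellet; pre-clearance too fast for a low-speed pellet; pellet
  speed between the windows).

Boundaries are taken literally from the stated inequalities (both pellet
cut-offs inclusive; the 10,000 x g pre-clearance threshold is inclusive for
sEV and strict for lEV). Free-text methods parsing and rpm-to-x g conversion
are out of scope: rpm values are rotor-dependent, so a protocol without x g
speeds is malformed input. Washes and gradients are notes, not rules. A
dataset reporting both fractions is two records with distinct ids.

## Identification-frequency statistics

Identifications are presence/absence: a dataset either identified a protein
or it did not. For each protein, `fsEV = k_sev/n_sev` and `flEV = k_lev/n_lev`
are the fractions of sEV and lEV datasets identifying it, and the effect
measure is `log2(fsEV/flEV)`. Because many proteins are absent from one
fraction entirely, the ratio is computed on Haldane–Anscombe-smoothed
frequencies, `log2(((k_sev+0.5)/(n_sev+1)) / ((k_lev+0.5)/(n_lev+1)))`, which
is always finite; the raw ratio is also emitted when both frequencies are
positive. The smoothing bias is bounded by `log2(1 + 0.5/min(k_sev, k_lev))`,
i.e. below 0.05 once both counts reach 20.

Per-protein differential identification uses a two-sided Fisher exact test on
`[[k_sev, n_sev-k_sev], [k_lev, n_lev-k_lev]]` with Benjamini–Hochberg
correction across proteins (both raw p and q are reported, since published
per-marker values are typically uncorrected). Marker panels (the bundled
fixture carries ten literature exosomal and ten ectosomal gene symbols) are
compared at the panel level with a Mann–Whitney U test of member `fsEV`
against member `flEV`. The Mann–Whitney implementation enumerates all
`C(n+m, n)` group assignments when the smaller group has at most 8
observations and there are no cross-group ties — exactness is cheap there —
and otherwise uses the tie-corrected normal approximation.

Proteins are partitioned at a threshold θ (default 0.1) on the smoothed
ratio: sEV-enriched (> θ), lEV-enriched (< −θ), balanced (|ratio| ≤ θ). The
partition is exhaustive and disjoint, and swapping the fraction labels
negates every ratio and mirrors the partition.

Protein identity is the upper-cased gene symbol; harmonising UniProt
accessions to symbols is the caller's responsibility. `ic_human` (the
identification count across the retained human datasets) is computed as
`k_sev + k_lev`; callers with a database-wide count can supply their own.

## Evolutionary conservation

Conservation of a protein is the number of prokaryotic (`IC_pro`, out of 141
datasets) and eukaryotic (`IC_eu`, out of 656) EV proteomic datasets that
identified one of its orthologs; ortholog grouping is precomputed upstream
and consumed as a table. The sEV-enriched and lEV-enriched groups (balanced
proteins excluded) are compared per kingdom with the Mann–Whitney U test on
raw counts — rank tests are invariant to the fixed normalisations
`IC_pro/141` and `IC_eu/656`, which are emitted only for plotting. Proteins
without a conservation record are excluded listwise rather than imputed as
zero: absent ortholog data is not evidence of absence. The biological
expectation is directional: ectosome budding is shared with prokaryotes, so
lEV-enriched proteins should carry higher `IC_pro`, while exosome biogenesis
through the endomembrane system is eukaryote-specific, favouring higher
`IC_eu` for sEV-enriched proteins.

## Interactome homophily and seed proteins

AP-MS edge lists are directed (bait → prey); Y2H lists are undirected and
stored once under lexicographic orientation. Self-loops are removed and
duplicate (bait, prey, assay) triples collapsed, keeping assay provenance.
Homophily is the Spearman correlation of the smoothed log2 ratio between the
endpoints of each unique interacting pair (AP-MS orientation preferred when
both assays support a pair); the p-value is the large-sample t approximation.
Whether to count an undirected edge in one or both orientations is a genuine
convention choice; single lexicographic inclusion was adopted, and a test
documents that reversing every Y2H edge moves rho by at most 0.02 at default
synthetic size.

"Seed proteins" — hubs that recruit their interactors into one EV subtype —
are formalised as neighbourhood enrichment: for each node with at least 10
partition-labelled neighbours, a one-sided hypergeometric test compares its
sEV- (and lEV-) enriched neighbour count against the network-wide labelled
composition, with BH correction across all (node, side) tests. The published
analysis presents exemplar subnetworks rather than a formal procedure; the
hypergeometric formalisation is this package's design. An `min_ic` filter
(identification count ≥ 50) matches the common practice of restricting
network views to well-observed proteins; it defaults to 0 for the
correlation and is exposed everywhere.

## Preranked GSEA

Implemented from scratch (an external implementation is used only as a test
oracle). Two ranked lists: all proteins by descending smoothed log2 ratio
(positive pole = sEV), and the balanced proteins (|ratio| ≤ θ) by
mean-centred `ic_human`. Ties order deterministically (score descending, id
ascending). For a set S in a list of N genes the running sum gains
`|score|^w / Σ_hits|score|^w` at members (weight w = 1 by default; w = 0
recovers the classic KS statistic) and loses `1/(N−|S|)` at non-members; ES
is the extreme deviation, with the positive pole chosen on an exact
magnitude tie. The null permutes gene-set membership: random equal-size sets
drawn from the ranked ids (one shared null per set size), `p_perm` one-sided
against the same-sign null with a +1 correction (hence slightly
conservative), `NES = ES / mean(|null ES| of the same sign)`, and FDR by the
sign-stratified ratio-of-tails estimator over pooled null NES, clipped to
[0, 1]. Defaults: 1000 permutations, set-size window [5, 500], all
configurable; phenotype permutation is impossible for preranked input.
Significant sets (FDR < 0.05) are exported with a Jaccard-overlap edge table
(threshold 0.5) for external cluster visualisation instead of rendered maps.

## Synthetic meta-studies

The generator emulates the statistical structure the analysis assumes, with
one seeded `numpy` generator and no global state. Defaults describe a
plausible desk-scale meta-study: 30 sEV + 30 lEV + 5 excluded datasets and
2000 proteins in four equal classes. Identification is Bernoulli per
(protein, dataset) with class/fraction rates EXO 0.6/0.1, ECTO 0.1/0.6,
SHARED 0.5/0.5, BACKGROUND 0.05/0.05; excluded datasets identify at the
class-mean rate so the matrix builder's dropping logic is exercised.
Conservation is binomial over the real dataset totals (141 prokaryotic, 656
eukaryotic) with per-class rates q_pro = {ECTO 0.15, EXO 0.05, SHARED 0.10,
BACKGROUND 0.05} and q_eu = {EXO 0.5, ECTO 0.3, SHARED 0.4, BACKGROUND 0.2},
ordered so the expected kingdom asymmetry is recoverable. The interactome is
a stochastic block model over the classes with weak background homophily
(within 0.008, between 0.004 — chosen so the bait–prey correlation lands in
the ~0.1–0.2 range reported for real integrated interactomes rather than an
unrealistically clean separation) plus three recruiter hubs per side wired
to 60 partners with probability 0.8 of staying within class; hubs must
dominate the background enrichment tail, which is what their high degree
encodes. Two planted gene sets (50 members inside EXO or ECTO) and eight
uniform decoys complete the study.

The generator does not model quantitative abundance, peptide-level
inference, missing-not-at-random acquisition, or inter-dataset correlation;
passing recovery tests therefore show the statistics behave correctly under
the stated generative assumptions, not that real EV meta-data satisfies
those assumptions.

## Numerical and testing choices

Exactness is tested against independent oracles: Fisher p against rational
hypergeometric enumeration on all 2×2 tables with margins ≤ 12, Mann–Whitney
against full assignment enumeration, neighbourhood hypergeometric p against
direct binomial-coefficient tail sums, and ES against an independent GSEA
implementation (1e-6). Repeated-seed recovery checks run at desk scale — 25
default-condition studies for classification/partition/conservation/
hub/gene-set recovery, and a three-point homophily grid with 50 seeds per
point for the correlation — sizes chosen as a practical compromise between
Monte-Carlo resolution and suite runtime. Null calibration asserts the
one-sided bound (rate ≤ 0.05 + 3 Monte-Carlo SE): both the Fisher test on
discrete presence counts and permutation p-values with the +1 correction are
conservative by construction, so a two-sided band around the nominal level
is not the right check. The pipeline's JSON summary contains no timestamps
and serialises with sorted keys and fixed float rounding, so a rerun with
the same config and seed is byte-identical.

## Known limitations

* Reproducing published headline numbers (a 51/203 dataset split, 3361/3028
  partition counts, Spearman rho = 0.1319) requires the originally curated
  protocol, conservation and interactome tables, which are not
  redistributable here; the package reproduces the procedures and verifies
  them on synthetic ground truth.
* Serial-pellet protocols keep only one retained pellet per record; datasets
  with multiple retained fractions must be split into multiple records.
* The Mann–Whitney asymptotic branch is approximate for small tied samples
  that fall outside the enumeration window.
* Seed-protein detection conditions on the ratio partition; proteins absent
  from the identification matrix cannot be hubs even if well connected.
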