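# Methods

This note records how each stage of the screening pipeline is defined,
the defaults and why, and the choices made where the design was open.

## Dataset preparation

An activity record is (id, structure, IC50 [nM], qualifier). Records
whose qualifier is anything but `exact` ("<", ">", "~") are unusable
for regression; those with an estimated value above the decoy threshold
(default 2000 nM) are kept separately as presumed-inactive decoys, the
rest are dropped. Records with exact values above the threshold remain
in the inhibitor set — they are genuine weak inhibitors and the
classifier needs them. Duplicates are detected by canonical structure
identity after desalting (largest organic fragment) and charge
neutralization; the mean is taken on the IC50 scale, not on pIC50,
before pIC50 = −log10(IC50·10⁻⁹) is derived. Screening libraries are
desalted and filtered to organic molecules (≥ 1 carbon) with MW ≥ 100
g/mol.

## Descriptors

* **khs.\*** — Kier–Hall E-state atom-type counts, via RDKit's E-state
  atom typer. Nitro nitrogen is counted as `ddsN` for both the charged
  and the pentavalent depiction.
* **ECCEN** — Σ over heavy atoms of eccentricity × degree, from the
  topological distance matrix. Disconnected input: largest fragment,
  with a warning.
* **SP6 / SPC4** — *simple* Kier–Hall chi indices (plain heavy-atom
  degrees, not valence-corrected). SP6 sums 1/√(Π degrees) over simple
  6-edge paths; SPC4 over connected 4-edge subgraphs classified as
  path-cluster (≥ 1 vertex of subgraph degree ≥ 3, excluding the pure
  star; pure paths and rings have no such vertex). Both are checked
  against exhaustive-enumeration oracles in the test suite.
* **GRAV4** — gravitational index. The base index is
  G = Σ_{i<j} m_i·m_j/r_ij² over heavy atoms of a single embedded
  conformer. Which transform of G the source models used is not
  documented anywhere we could find, so the variant is configurable
  (G1 = G, G2 = √G, G3/G4 = ∛G, G5/G6 = bonded-pair analogues) with
  ∛G over all pairs as the default; the choice is recorded in output
  metadata. The published regression validates on worked examples with
  supplied descriptor values, so the scale choice does not affect the
  packaged-equation arithmetic.
* **DPSA3** — charge-weighted positive minus charge-weighted negative
  solvent-accessible surface area. Charges are Gasteiger; areas come
  from an in-package Shrake–Rupley implementation: probe 1.4 Å, Bondi
  radii, a fixed 960-point golden-spiral grid per atom. The fixed grid
  makes values bit-reproducible and exactly translation-invariant;
  rotation invariance holds only to the grid's angular resolution
  (≈ 1 % relative), which is the accepted cost of determinism.
* **MDEN13** — molecular distance edge over (primary N, tertiary N)
  pairs: n/g², g = (Π pairwise topological distances)^(1/(2n)); 0 when
  no pair exists.
* **C2SP2/C2SP3/C3SP2** — carbon hybridization/carbon-neighbour counts;
  **nAcid** counts carboxylic, sulfonic and phosphonic acid groups by
  explicit SMARTS (listed in `descriptors.py`); MW, ALogP
  (Ghose–Crippen as implemented by RDKit), TPSA, HBD/HBA, rotatable
  bonds by RDKit's standard definitions.
* **3D embedding** — ETKDGv3 with a caller-supplied seed (default 42),
  MMFF minimization, fallback seed list on embedding failure.

## Scaffolds and features

Bemis–Murcko skeletons keep rings and linkers, erase atom and bond
types, and drop side chains; genericization is followed by a second
side-chain strip so that former carbonyl oxygens do not linger as
methyl stubs (this makes the operation idempotent). Plain ring systems
keep atom/bond types and retain atoms attached to the ring by a double
bond — without this, dione-type cores would lose their carbonyls and
collapse onto plain heterocycles. Most-central rings are those at
minimal topological distance from the graph center (minimum-eccentricity
heavy atoms); all tied rings are returned, and a most-central-ring
feature matches via any of them. Feature identity is canonical-SMILES
equality of the extracted ring graphs, not substructure matching, so
benzene stays distinct from fused aromatics. The shipped feature
library (`data/feature_library.json`) holds the TRPA1 feature set:
three BM skeletons, eight plain rings, the thiazole most-central ring
and thirteen atom groups; the scoring subset is the twelve
high-activity features. For bicyclic library entries (PR-1…PR-5) the
detector also matches whole plain-ring systems, since splitting them
into individual rings would destroy their identity.

## SAR statistics

Feature enrichment uses a two-sample Student *t*-test (pooled variance,
the classic statistical-package default; Welch selectable), significance
at *p* < 0.01. Features present in all or no compounds are excluded;
zero-variance comparisons are flagged untestable. The weighted index
is |Δmean|/pooled range; the per-descriptor AUC is the Mann–Whitney
rank statistic oriented to ≥ 0.5. The similarity metric behind pair
and activity-cliff mining is pluggable (the original study used a
proprietary 3D pharmacophore-graph descriptor); the default is a
Morgan-fingerprint Tanimoto, and the 0.80 threshold is configurable —
absolute thresholds do not transfer between metrics. The activity-cliff
potency gap is not documented in the source; the default |ΔpIC50| ≥ 2
is an explicit stand-in.

## Mining score and selection

One point per scoring feature present plus one similarity point;
selection keeps score ≥ 3. The two published phrasings (similarity
plus ≥ 2 features / no similarity plus ≥ 3 features) are both exactly
this single threshold. Maximum score under defaults: 13.

## Classifier

Classes: weak (pIC50 < 6) = 0, strong (pIC50 > 7) = 1; moderates,
including the exact boundary values, are excluded from training
(the source states strict inequalities). Descriptor selection:
*t*-test significance → weighted index > 0.2 → AUC > 0.8 → greedy
pruning of |r| > 0.9 pairs keeping the higher-AUC member. Cutoffs
maximize Youden J (the "balanced sensitivity/specificity" ROC
coordinate), ties resolved toward the midpoint of the class means.
The published model's combination rule is not stated; it is
implemented as a configurable vote with default ≥ 3 of 4, and the
ordinal vote count (0–4) serves as the score for a single global ROC.

## Regression

Forward selection adds the descriptor with the smallest partial-F
p-value while p < 0.01; stepwise additionally removes included terms
whose p-value rises above 0.05 (the removal-band ceiling). "10-fold
bootstrapping" is read as ten independent random 70/30 resplits (not
cross-validation folds); the best model is the one with highest
predictive R² (squared Pearson correlation on the test split),
tie-broken by lower RMSE. Collinear candidates never enter (their
partial F is undefined); duplicated columns therefore survive only
once. The published equation duplicates DPSA3 with the classifier —
a known overfitting caveat of the source models, left as-is.

## Ranking and BBB filter

The logistic model is fit by maximum likelihood (statsmodels); perfect
separation is flagged and coefficients are capped rather than allowed
to diverge. Probability is strictly increasing in predicted pIC50 and
class, and decreasing in ΔG (more negative binding energy → higher P)
under the published signs. Ranking ties break by mining score then id,
so output files are deterministic. BBB boundary semantics: "under" is
strict (<), ranges and "or fewer" are inclusive; the rules are
monotone per property. Docking scores are consumed as an input column
only — no docking engine is run or wrapped.

## Synthetic data

The generator assembles molecules from a ~30-fragment grammar (cores
carrying the library's ring features, substituents carrying atom
groups) and draws pIC50 = baseline + Σ feature effects + N(0, σ).
Defaults mirror the reference study's shapes: 371 inhibitors, 76
censored decoys; baseline 5.3, σ = 0.5, and per-feature effects of
0.8–1.5 pIC50 units chosen to match the enrichment magnitudes the SAR
analysis reports. Simulated docking scores are drawn from N(−7.3, 1.0)
truncated to [−10.4, −4.1] kcal/mol, the range reported for druglike
libraries. What the generator does **not** emulate: real medicinal-
chemistry diversity, correlated descriptor structure, assay noise
heteroscedasticity, or similarity clustering — so passing recovery
tests demonstrates the statistical machinery is correct, not that the
packaged models generalize to new chemistry.

## Test and validation sizes

Statistical tests use planted-signal recovery at the sizes stated with
each property (n = 100–1000 observations, 500 null simulations for
type-I control); the end-to-end pipeline tests run on synthetic sets of
30–60 molecules, which exercise every stage (3D embedding included) in
seconds. Published-model arithmetic is checked against the printed
worked examples; two of the ten ranking-table probabilities differ from
the printed values by 5.6–6.9×10⁻⁴ because the printed inputs (pIC50 to
two decimals, ΔG to one) are themselves rounded — the strict 5×10⁻⁴
check for those two rows is expected to fail and is retained as-is.

## Known limitations

* The plain-ring and most-central-ring dialects of the original
  desktop software are reimplemented from their textual definitions;
  ring-perception corner cases (e.g. large fused cages) may differ.
* GRAV4's exact transform and the ALogP scheme of the BBB filter are
  undocumented in the source; both are pinned and recorded here.
* The similarity stage is metric-pluggable by necessity; scores from
  the default fingerprint metric are not comparable to 3D
  pharmacophore-graph similarities.
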