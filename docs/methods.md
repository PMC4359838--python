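# Methods

## The model

`ltmclust` analyses a records × symptoms matrix of binary clinical
manifestations with a **latent tree model** (LTM, also called a hierarchical
latent class model or latent structural model): a rooted tree-structured
Bayesian network whose leaves are the observed 0/1 manifest variables and
whose internal nodes are unobserved discrete latent variables. The root
carries a marginal distribution over its states; every other node carries a
CPT of its states given each parent state. Each latent variable clusters the
records along one dimension; different latent variables capture different,
co-existing ways of partitioning the same patients — which is what makes the
model family attractive for syndrome differentiation, where one patient
simultaneously expresses several syndromic axes.

Inference is exact sum-product on the tree, vectorised over records, with
per-record scaling to avoid underflow. CPT values are floored at 1e-12 during
inference (configurable) so that sampling-zero cells cannot produce `log(0)`.
Log-likelihoods are in nats; mutual information is reported in bits, the
convention for information curves.

A brute-force oracle (`model.full_joint` / `enumerate_joint`) materialises the
complete factored joint as a dense tensor, with no message passing in the code
path. Every inferential quantity (likelihood, posteriors, pairwise and joint
MI) is tested against it to 1e-9 on hundreds of random models of up to 12
variables; the oracle refuses joints above 2^20 cells and larger queries fall
back to seeded Monte-Carlo estimation.

## Parameter estimation (EM) and model score

For a fixed structure, parameters are fitted by expectation–maximisation:
the E-step is exact tree inference; the M-step sets each CPT row to the ratio
of expected counts with an additive pseudo-count of 0.01 per cell (sparse
cells are common at a 559-record scale). With the pseudo-count the quantity
EM provably never decreases is the lightly regularised objective
`loglik + 0.01 · Σ log θ`; that objective is what `EMResult.loglik_trace`
records and what convergence (relative change < 1e-6, default) is measured
on. The raw data log-likelihood of the final model is reported separately.

Restarts (default 8 for stand-alone fits; fewer inside the structure search)
draw every CPT row from a symmetric Dirichlet(1.0) with seeds spawned
deterministically from the caller's seed; ties across restarts go to the
lowest restart index. Structures are scored by
`BIC = loglik − (d/2)·ln N` with `d = Σ_node (card−1)·card(parent)`.

## Structure search

`search_structure` hill-climbs on BIC in the spirit of the
expansion–adjustment–simplification family of LTM searches:

* **expansion** — *node introduction*: a new 2-state latent is inserted
  between a latent node and a pair of its children. A bare introduction
  usually sits in a BIC valley (it pays off only once the other strongly
  associated siblings follow the pair), so the candidate that is scored for
  acceptance is the *enriched* one: introduction followed by greedy
  relocations of siblings into the new latent while a cheap screened BIC
  improves. *State introduction* raises a latent's cardinality by one
  (bounds 2..5 by default).
* **adjustment** — relocation of any non-root node to a different latent
  parent (tree-ness and leaf-ness preserved; cycle-creating moves rejected).
* **simplification** — state deletion and node deletion (a deleted latent is
  collapsed exactly: each child's warm-start CPT is the matrix product
  through the deleted node).

Candidate generation is pruned by empirical mutual information between node
"signatures" (raw columns for manifests, max-posterior imputed states for
latents); the top candidates are screened with a short warm-started EM
(tol 1e-4, 30 iterations, 1 restart) and the best few are re-fit with the
full budget; a move is accepted only if the fully fitted BIC strictly
improves, so the search terminates. Ties among equal-BIC candidates break
lexicographically, and all seeds derive from the search seed, so runs are
reproducible. The search starts from the flat single-latent model and, with
two manifest columns, returns it unchanged (the only topology).

Known limitation: a planted block with a single member can never be
recovered — a latent with one child always loses BIC to its collapse — so
leaf-partition recovery is only expected for multi-member blocks. Greedy
search also finds local optima: on the full 57-column preset at n = 559 it
typically returns fewer latent variables than the 14 planted blocks, because
the weakly loaded satellite manifestations carry too little signal at that
sample size.

## Information curves and the 95% coverage rule

A latent variable Y is interpreted by ordering the manifest variables by
pairwise MI I(Y;X) (descending, ties alphabetical), accumulating the joint MI
I(Y; X₁..X_k) along that order, and reporting **information coverage**
`100 · I(Y; X₁..X_k) / I(Y; scope)`. The shortest prefix whose coverage
reaches the threshold (95% by default) is the latent's significant
manifestation list. Coverage is scale-free (a change of MI units cancels),
the final entry's coverage is 100 by construction, and a latent with zero
total information raises a degenerate-latent error.

MI is computed from the fitted model distribution, not from empirical cell
counts (the curves are attributes of the model; an empirical mode via
max-posterior imputation is not provided in this release). Cumulative MI is
exact — enumeration of the 2^k manifest configurations — up to 2^16
configurations inside curve construction (2^20 for stand-alone calls), and a
seeded Monte-Carlo estimator `mean[log₂ p(y|x) − log₂ p(y)]` (20 000 samples
by default, standard error reported) beyond; all Monte-Carlo prefixes of one
curve share a single sample set and the cumulative sequence is made
non-decreasing by running maximum, which only ever corrects Monte-Carlo
noise. Coverage for per-latent curves is normalised over **all** manifest
variables of the model by default; a per-latent children-only scope is
available (`scope="children"`).

## Joint clustering, exclusions, sub-syndromes

A **syndrome factor** is a named, expert-declared grouping of latent
variables with an optional exclusion list; the five factors of the liver
cancer study (Qi-stagnation, dampness, blood-stasis, heat, deficiency of
healthy-Qi over Y0–Y13) ship as `study_factor_map()`. For a factor, the
significant manifestations of its member latents are pooled (ordered union)
and a fresh latent class variable Z is fitted flat over the pooled raw
columns — the joint clustering model. Z's cardinality is chosen by BIC within
2..5 (4 restarts per cardinality, ties to the smaller); Z's information curve
is scoped to the pool; the factor's typical manifestations are the 95%
selection minus the exclusions. Exclusions are purely declarative — the
software never auto-excludes — and are applied to the factor's selection and
to its sub-syndrome selections (the study excludes one manifestation at the
sub-syndrome level).

When Z has three or more states the factor splits: the state with the lowest
mean manifestation probability is the baseline, and each pooled manifest is
assigned to the non-baseline state maximising its lift
`P(m=1|Z=s)/P(m=1)` (threshold 1.0, ties to the earlier state) — a
reproducible quantitative surrogate for what the study decided by expert
judgement. Lift-based assignment is invariant to relabelling Z's states. One
sub-JCM per sub-syndrome is re-fit over its manifest set (cardinality by BIC
within 2..3) and its curve and selection are reported. An alternative
hierarchical JCM topology (Z as parent of re-fit member latents) was
considered and not implemented: the flat model is identifiable, testable and
matches the curve semantics.

## The synthetic cohort generator

No patient-level data are deposited, so the pipeline is exercised on cohorts
sampled (ancestrally, seeded) from planted models. `PlantedSpec` declares
blocks (latent name, cardinality, member manifests with loading strengths or
explicit activation profiles), an optional latent–latent backbone (scalar
couplings or explicit CPTs), a record count, demographic tag distributions
and a seed. Loading strength *s* means the activation probability spread
across latent states is exactly *s*. Mutually independent blocks are joined
under a neutral uniform root so the model stays a single tree.

`study_cohort_preset()` emulates the study cohort: 559 records, the 57
manifestations in the study's listing order, 14 latent blocks matching the
reported groupings (the 16 manifestations the study does not assign are
attached as weak satellites of the clinically closest block), and sex/stage
tag proportions matching the reported 482/77 and 66/72/92/171/139/19 splits.
Tags are generated but never modelled.

The preset's default backbone and loading profile are *designed*, by exact
model-side information-curve computation, so that the documented qualitative
behaviours of the analysis hold on the synthetic cohort: a two-manifest
latent (fever / hectic fever) whose two strong members alone reach 95%
coverage; a Qi-stagnation joint clustering whose selection is a seven-item
list containing the two expert-excluded manifestations; and a deficiency
factor whose Z genuinely has three conditions (a 3-state hub latent drives
Y2/Y3 in one non-baseline state and Y11/Y12 in the other) and therefore
splits into exactly two sub-syndromes. This required deviating from the
simplest design (a uniformly weakly coupled chain with one loading value):
uniform strong loadings saturate cumulative MI so the 95% rule truncates
blocks early, and a weak chain cannot produce a three-condition factor at
all. The margins were set against exact coverage profiles (e.g. the
Qi-stagnation pool covers 89.8% at six entries and 98.8% at seven on the true
model), then frozen. At n = 559 the fitted-model coverage fluctuates a few
points around these values, so on a small fraction of cohort seeds the
seven-item selection closes at six; this is irreducible sampling variance of
a 559-record cohort, not a software defect. `study_cohort_preset(strength=s)`
switches to the clean benchmark configuration — every latent binary, every
member loading *s*, a weakly coupled (0.1) chain backbone in block order —
used for structure-recovery experiments.

## Pipeline, seeds, determinism

`run_pipeline` stages: load/simulate → frequency screen (`min_count` is an
explicit parameter; the study's exact cutoff is unstated) → establish the
LSM → per-latent curves → per-factor joint clustering → run manifest.
Because a factor map is authored against the latent names of one specific
model (the study's Y0–Y13 exist only relative to its fitted tree, and a
singleton block like Y0 is unlearnable by any BIC search), the curve and
factor stages run on a **base model**: a supplied structure re-fit by EM on
the cohort when `base_model_path` is given (the preset run supplies the
planted structure), otherwise the learned model. The search still runs as
its own stage (`learn_structure`) and its model, DOT rendering and move
trace are part of the report bundle.

All randomness flows from one master seed through named per-stage seeds
(`SeedSequence([master, stage_index])`); outputs contain no timestamps or
machine entropy, so identical config + seed reproduces every output byte for
byte. Degenerate latents are skipped in the curves stage with a notice;
stage failures abort with the stage name attached and partial outputs
preserved.

Default problem sizes were chosen to keep a full desk run short: the
200-model oracle sweep runs in seconds; planted-recovery benchmarks use
3 blocks × 4 leaves at n = 2000 (10 seeds) and n = 5000 for parameter and
cardinality recovery; the routine-test round trip uses a four-block,
16-manifest reduction of the preset at n = 1500; the full preset pipeline
takes a few minutes on one core.

## What passing on synthetic data does and does not show

The generator plants conditionally independent members within blocks, weak
cross-block couplings, and i.i.d. records. Real symptom data have
comorbidity-driven dependence that no tree over one layer of latents
captures, informative missingness (rejected here by design), coding error,
and prevalences unknown for the study cohort (the preset's marginals are
declared synthetic defaults, not estimates). Passing the recovery and
fixture tests therefore shows the *machinery* is correct — inference exact,
EM monotone, search consistent on identifiable structure, curve and
clustering rules implemented as documented — not that a 14-latent model is
the right description of any clinical population.
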