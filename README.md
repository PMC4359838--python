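# ltmclust

Latent tree analysis of binary clinical manifestation data: learn a tree of
discrete latent variables over 0/1 symptom indicators, interpret each latent
variable through mutual-information curves with an information-coverage rule,
and jointly cluster latent variables that share a *syndrome factor* into
typical-manifestation lists — the unsupervised workflow used in traditional
Chinese medicine syndrome differentiation research, here applied to a
synthetic cohort shaped like a 559-patient primary-liver-cancer symptom
survey (57 binary manifestations).

## The model and the analysis

A **latent tree model** is a rooted tree-structured Bayesian network: leaves
are observed binary manifest variables X₁..X_M, internal nodes are discrete
latent variables Y with CPTs P(node | parent). Parameters are estimated by
EM (exact sum-product E-step); structure is learned by a greedy BIC-guided
search with node-introduction, state-adjustment, relocation and
simplification operators, where

    BIC(m) = log L(m) − (d/2)·ln N,   d = Σ_node (card−1)·card(parent).

Each latent Y is interpreted by its **information curve**: manifests ordered
by pairwise mutual information I(Y;X), a cumulative curve I(Y;X₁..X_k) above
it, and *information coverage* 100·I(Y;X₁..X_k)/I(Y;all). The shortest prefix
reaching 95% coverage is Y's significant manifestation list. For each
syndrome factor (an expert-declared set of latents, e.g. Qi-stagnation ↦
{Y0, Y1, Y9}), the members' significant manifestations are pooled, a fresh
latent class variable Z is fitted over the pooled columns (cardinality by
BIC), and Z's curve — minus declarative expert exclusions — yields the
factor's typical manifestations; a Z with ≥3 states splits into one
sub-syndrome per non-baseline state by activation lift.

Because the clinical data were never deposited, a first-class synthetic
module generates cohorts from *planted* latent tree models (14 blocks,
57 manifestations, 559 records in the study-shaped preset) so that every
stage is testable against a known truth.

## Worked example

Run the staged analysis (each script is a thin driver over the library and
writes under `results/`):

    python analysis/01_simulate_cohort.py --seed 1
    python analysis/02_learn_structure.py --seed 1
    python analysis/03_information_curves.py --seed 1
    python analysis/04_joint_clustering.py --seed 1

The first script prints the cohort shape and prevalence head:

    cohort: 559 records x 57 manifestations
    sex: {'male': 477, 'female': 82}

The third prints each latent variable's 95%-coverage selection, e.g.

    Y8: 2 manifestation(s) reach 95% coverage: fever, hectic fever

— two manifestations suffice to reflect this latent variable, so the curve
truncates there. The fourth prints the factor reports:

    Qi-stagnation (Z1, 2 states): typical manifestations = hypochondriac pain,
        chest distress, abdominal distension, stomachache, stomach bloating
    deficiency (Z5, 3 states): typical manifestations = thready pulse, ...
      sub-syndrome Z5a: lumbar genu aching and limp, fatigue,
        dry mouth and throat, heat in palms and soles, insomnia, night urination
      sub-syndrome Z5b: night sweating, tinnitus, dim complexion,
        sallow complexion, anorexia, loose stool, weak pulse

Z1's raw selection has seven manifestations; the shipped exclusion list
(chills, dizziness — expert judgements, applied declaratively) reduces it to
the five shown. Z5's three states mean the deficiency factor divides into two
sub-syndromes: Z5a collects the liver/kidney-yin-style complaints, Z5b the
spleen/kidney-yang-style ones.

The same workflow is available as one command:

    ltmclust run --seed 0 --out results/run        # simulates the preset
    ltmclust simulate --preset study --seed 7 --out cohort.csv
    ltmclust fit cohort.csv --seed 1 --out model.json
    ltmclust curves model.json --latent Y8 --out y8.tsv
    ltmclust jointcluster model.json cohort.csv --factor deficiency --out z5.tsv

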