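"""Joint clustering of latent variables that share a syndrome factor.

A *syndrome factor* is a named grouping of latent variables (declared by
domain experts, consumed here as configuration). For each factor the evidence
of its member latents - the union of their significant manifests - is pooled,
and a fresh latent class variable Z is fitted over the pooled columns (the
"flat" joint clustering model, JCM). Z's information curve over the pooled
scope yields the factor's typical manifestations after declarative expert
exclusions are applied. When BIC assigns Z three or more states, the factor
splits into one sub-syndrome per non-baseline state and sub-JCMs are re-fit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .curves import InformationCurve, information_curve, select_significant
from .data import SymptomMatrix
from .em import EMResult, bic_score, fit_em
from .errors import ConfigurationError
from .model import LatentTreeModel, latent_class_skeleton, node_marginals

logger = logging.getLogger(__name__)

__all__ = [
    "FactorSpec",
    "SyndromeFactorMap",
    "study_factor_map",
    "SubSyndrome",
    "JointClusteringModel",
    "apply_exclusions",
    "choose_cardinality",
    "build_jcm",
    "subdivide",
]


@dataclass(frozen=True)
class FactorSpec:
    latents: tuple[str, ...]
    exclusions: tuple[str, ...] = ()


@dataclass
class SyndromeFactorMap:
    """Named syndrome factors -> member latent variables + expert exclusions."""

    factors: dict[str, FactorSpec]

    def validate(self, model: LatentTreeModel) -> None:
        latents = set(model.latent_names)
        for name, spec in self.factors.items():
            missing = [y for y in spec.latents if y not in latents]
            if missing:
                raise ConfigurationError(
                    f"factor {name!r} references unknown latent(s) {missing}"
                )

    def to_json_dict(self) -> dict:
        return {
            name: {"latents": list(s.latents), "exclusions": list(s.exclusions)}
            for name, s in self.factors.items()
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1), "utf-8")

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyndromeFactorMap":
        return cls(
            {
                name: FactorSpec(tuple(s["latents"]), tuple(s.get("exclusions", ())))
                for name, s in d.items()
            }
        )

    @classmethod
    def load(cls, path: str | Path) -> "SyndromeFactorMap":
        return cls.from_json_dict(json.loads(Path(path).read_text("utf-8")))


def study_factor_map() -> SyndromeFactorMap:
    """The study's five syndrome factors over latents Y0-Y13.

    Exclusion lists are the study's declarative expert judgements; the
    deficiency factor's exclusion applies at the sub-syndrome level.
    """
    return SyndromeFactorMap(
        {
            "Qi-stagnation": FactorSpec(("Y0", "Y1", "Y9"), ("chills", "dizziness")),
            "dampness": FactorSpec(("Y5", "Y9", "Y13")),
            "blood-stasis": FactorSpec(
                ("Y0", "Y2", "Y4", "Y7", "Y9"), ("slippery pulse", "plump tongue")
            ),
            "heat": FactorSpec(("Y8", "Y12", "Y13")),
            "deficiency": FactorSpec(
                ("Y2", "Y3", "Y10", "Y11", "Y12"), ("bitter taste",)
            ),
        }
    )


def apply_exclusions(
    selected: Sequence[str], exclusions: Sequence[str]
) -> list[str]:
    """Ordered set difference; exclusions not present are ignored with a notice."""
    exc = set(exclusions)
    absent = [e for e in exclusions if e not in selected]
    if absent:
        logger.info("exclusions not in selection (ignored): %s", absent)
    out = [s for s in selected if s not in exc]
    if not out and selected:
        logger.warning("exclusion list removed every selected manifestation")
    return out


@dataclass
class CardinalityChoice:
    cardinality: int
    bics: dict[int, float]
    results: dict[int, EMResult] = field(repr=False, default_factory=dict)


def choose_cardinality(
    data: SymptomMatrix,
    columns: Sequence[str],
    bounds: tuple[int, int] = (2, 5),
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 200,
    restarts: int = 4,
    latent_name: str = "Z",
) -> CardinalityChoice:
    """BIC-maximizing cardinality for a latent class variable over ``columns``.

    Deterministic given ``seed``; ties go to the smaller cardinality.
    """
    lo, hi = bounds
    if not (2 <= lo <= hi <= 5):
        raise ConfigurationError("cardinality bounds must lie within (2, 5)")
    sub = data.subset(list(columns))
    seeds = np.random.SeedSequence(seed).generate_state(hi - lo + 1, dtype=np.uint32)
    bics: dict[int, float] = {}
    results: dict[int, EMResult] = {}
    for i, card in enumerate(range(lo, hi + 1)):
        skel = latent_class_skeleton(sub.symptoms, card, latent_name)
        res = fit_em(
            skel, sub, tol=tol, max_iter=max_iter, restarts=restarts,
            seed=int(seeds[i] & 0x7FFFFFFF),
        )
        bics[card] = bic_score(res.model, sub, res.loglik)
        results[card] = res
    best = max(bics, key=lambda c: (bics[c], -c))
    return CardinalityChoice(best, bics, results)


@dataclass
class SubSyndrome:
    name: str
    state: int
    manifests: list[str]
    model: LatentTreeModel | None
    curve: InformationCurve | None
    selected: list[str]


@dataclass
class JointClusteringModel:
    factor: str
    z_name: str
    member_latents: list[str]
    pooled_manifests: list[str]
    cardinality: int
    bics: dict[int, float]
    model: LatentTreeModel
    curve: InformationCurve
    selected_raw: list[str]   # significant list before exclusions
    selected: list[str]       # after exclusions
    subsyndromes: list[SubSyndrome] = field(default_factory=list)

    def report_lines(self) -> list[str]:
        lines = [
            f"factor\t{self.factor}",
            f"latent\t{self.z_name}",
            f"members\t{','.join(self.member_latents)}",
            f"cardinality\t{self.cardinality}",
            f"selected\t{','.join(self.selected)}",
        ]
        for s in self.subsyndromes:
            lines.append(f"subsyndrome:{s.name}\t{','.join(s.selected)}")
        return lines


def build_jcm(
    base: LatentTreeModel,
    data: SymptomMatrix,
    factor: str,
    fmap: SyndromeFactorMap,
    z_name: str | None = None,
    threshold: float = 95.0,
    scope: str = "all",
    cardinality_bounds: tuple[int, int] = (2, 5),
    seed: int = 0,
    curve_seed: int = 0,
    subdivide_factors: bool = True,
) -> JointClusteringModel:
    """Fit the joint clustering model of one syndrome factor.

    ``scope`` controls the coverage normalisation of the member latents'
    curves ("all" manifests of the base model, or "children" for each
    latent's own leaf descendants). The Z curve itself is always scoped to
    the pooled manifests.
    """
    if factor not in fmap.factors:
        raise ConfigurationError(f"unknown factor {factor!r}")
    spec = fmap.factors[factor]
    if not spec.latents:
        raise ConfigurationError(f"factor {factor!r} has no member latents")
    fmap.validate(base)

    pooled: list[str] = []
    for latent in spec.latents:
        latent_scope = (
            base.manifest_names if scope == "all" else base.leaf_descendants(latent)
        )
        curve = information_curve(base, latent, latent_scope, seed=curve_seed)
        for m in select_significant(curve, threshold):
            if m not in pooled:
                pooled.append(m)
    if not pooled:
        raise ConfigurationError(f"factor {factor!r} pooled no manifests")

    z = z_name or f"Z[{factor}]"
    choice = choose_cardinality(
        data, pooled, bounds=cardinality_bounds, seed=seed, latent_name=z
    )
    fitted = choice.results[choice.cardinality].model
    zcurve = information_curve(fitted, z, pooled, seed=curve_seed)
    selected_raw = select_significant(zcurve, threshold)
    selected = apply_exclusions(selected_raw, spec.exclusions)

    jcm = JointClusteringModel(
        factor=factor,
        z_name=z,
        member_latents=list(spec.latents),
        pooled_manifests=pooled,
        cardinality=choice.cardinality,
        bics=choice.bics,
        model=fitted,
        curve=zcurve,
        selected_raw=selected_raw,
        selected=selected,
    )
    if subdivide_factors and choice.cardinality >= 3:
        jcm.subsyndromes = subdivide(
            jcm, data, exclusions=spec.exclusions, threshold=threshold, seed=seed
        )
    return jcm


def subdivide(
    jcm: JointClusteringModel,
    data: SymptomMatrix,
    exclusions: Sequence[str] = (),
    threshold: float = 95.0,
    seed: int = 0,
    lift_threshold: float = 1.0,
) -> list[SubSyndrome]:
    """Split a >=3-state JCM into one sub-syndrome per non-baseline state.

    The baseline state is the one with the lowest mean manifestation
    probability; every pooled manifest is assigned to the non-baseline state
    maximising its lift P(m=1 | Z=state) / P(m=1) (ties to the earlier state,
    manifests whose best lift is <= ``lift_threshold`` stay unassigned).
    Assignment by lift is invariant to relabeling Z's states.
    """
    if jcm.cardinality < 3:
        logger.info("JCM %s has cardinality 2; nothing to subdivide", jcm.z_name)
        return []
    model = jcm.model
    z = jcm.z_name
    marg = node_marginals(model)
    cols = jcm.pooled_manifests
    # P(m=1 | z=s): chain from z (the root of the flat JCM) to each leaf
    p_given = {m: model.cpts[m][:, 1] for m in cols}
    p_marg = {m: float(marg[m][1]) for m in cols}
    mean_active = np.array(
        [np.mean([p_given[m][s] for m in cols]) for s in range(jcm.cardinality)]
    )
    baseline = int(mean_active.argmin())
    states = [s for s in range(jcm.cardinality) if s != baseline]

    assignment: dict[int, list[str]] = {s: [] for s in states}
    for m in cols:
        lifts = [(p_given[m][s] / max(p_marg[m], 1e-12), s) for s in states]
        best_lift, best_state = max(lifts, key=lambda t: (t[0], -t[1]))
        if best_lift > lift_threshold:
            assignment[best_state].append(m)

    subs: list[SubSyndrome] = []
    sub_seeds = np.random.SeedSequence([seed, 97]).generate_state(
        len(states), dtype=np.uint32
    )
    for i, s in enumerate(states):
        name = f"{jcm.z_name}{chr(ord('a') + i)}"
        manifests = assignment[s]
        if len(manifests) < 2:
            logger.warning(
                "sub-syndrome %s has %d manifest(s); no sub-model fitted",
                name, len(manifests),
            )
            subs.append(SubSyndrome(name, s, manifests, None, None,
                                    apply_exclusions(manifests, exclusions)))
            continue
        choice = choose_cardinality(
            data, manifests, bounds=(2, 3),
            seed=int(sub_seeds[i] & 0x7FFFFFFF), latent_name=name,
        )
        sub_model = choice.results[choice.cardinality].model
        curve = information_curve(sub_model, name, manifests, seed=seed)
        sel = apply_exclusions(select_significant(curve, threshold), exclusions)
        subs.append(SubSyndrome(name, s, manifests, sub_model, curve, sel))
    return subs
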