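"""Information curves: interpreting a latent variable by its manifests.

For a latent variable Y the manifest variables are ordered by pairwise mutual
information I(Y; X) (descending), the cumulative joint mutual information
I(Y; X_1..X_k) is accumulated along that order, and *information coverage* is
the cumulative MI of the first k manifests as a percentage of the cumulative
MI of the whole scope. The analysis truncates the list at the first k whose
coverage reaches a threshold (95% by default): those are the latent's
significant manifestations.

All MI values are reported in bits. Pairwise MI and (for scopes of up to
``exact_limit`` manifests) cumulative MI are computed exactly from the model
distribution; larger scopes fall back to a seeded Monte-Carlo estimator of
I(Y; X) = E[log2 p(Y|X) - log2 p(Y)] with a reported standard error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateLatentError, SchemaError
from .model import (
    LatentTreeModel,
    mutual_information,
    node_marginals,
    pair_marginal,
    posteriors,
    sample_model,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CurveEntry",
    "InformationCurve",
    "pairwise_mi",
    "cumulative_mi",
    "information_curve",
    "select_significant",
]

EXACT_LIMIT = 2 ** 20  # largest manifest-configuration table enumerated exactly


def pairwise_mi(model: LatentTreeModel, latent: str, manifest: str) -> float:
    """Exact I(latent; manifest) in bits under the model distribution."""
    return mutual_information(pair_marginal(model, latent, manifest))


def _exact_joint_mi(model: LatentTreeModel, latent: str, manifests: Sequence[str]) -> float:
    """I(Y; X_1..X_k) by exact enumeration of the 2^k manifest configurations."""
    k = len(manifests)
    configs = ((np.arange(2 ** k)[:, None] >> np.arange(k)[::-1]) & 1).astype(np.int64)
    ev = {m: configs[:, i] for i, m in enumerate(manifests)}
    post, _, ll = posteriors(model, ev)
    p_cfg = np.exp(ll)
    p_y = node_marginals(model)[latent]
    q = post[latent]
    mask = q > 0
    ratio = np.where(mask, q / np.maximum(p_y[None, :], 1e-300), 1.0)
    mi = (p_cfg[:, None] * np.where(mask, q * np.log(ratio), 0.0)).sum()
    return max(float(mi) / math.log(2.0), 0.0)


def _mc_joint_mi(
    model: LatentTreeModel,
    latent: str,
    manifests: Sequence[str],
    samples: dict[str, np.ndarray],
) -> tuple[float, float]:
    """Monte-Carlo I(Y; X_1..X_k) from pre-drawn joint samples, with SE."""
    n = len(samples[latent])
    ev = {m: samples[m] for m in manifests}
    post, _, _ = posteriors(model, ev)
    p_y = node_marginals(model)[latent]
    y = samples[latent]
    num = np.maximum(post[latent][np.arange(n), y], 1e-300)
    den = np.maximum(p_y[y], 1e-300)
    vals = (np.log(num) - np.log(den)) / math.log(2.0)
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n))


def cumulative_mi(
    model: LatentTreeModel,
    latent: str,
    manifests: Sequence[str],
    exact_limit: int = EXACT_LIMIT,
    n_samples: int = 30000,
    seed: int = 0,
    return_se: bool = False,
):
    """Joint mutual information I(latent; manifests) in bits.

    Exact when 2^k fits in ``exact_limit``; otherwise a seeded Monte-Carlo
    estimate. With ``return_se=True`` returns (value, standard_error), the
    SE being 0.0 on the exact path.
    """
    manifests = list(manifests)
    if not manifests:
        raise SchemaError("cumulative_mi needs at least one manifest")
    for m in manifests:
        if m not in model.variables or model.variables[m].kind != "manifest":
            raise SchemaError(f"{m!r} is not a manifest variable of the model")
    if 2 ** len(manifests) <= exact_limit:
        val, se = _exact_joint_mi(model, latent, manifests), 0.0
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        samples = sample_model(model, n_samples, rng)
        val, se = _mc_joint_mi(model, latent, manifests, samples)
    return (val, se) if return_se else val


@dataclass(frozen=True)
class CurveEntry:
    manifest: str
    pairwise_mi: float   # bits
    cumulative_mi: float  # bits, over the prefix ending at this entry
    coverage: float      # percent of the full-scope cumulative MI


@dataclass
class InformationCurve:
    """Ordered information curve of one latent variable over a scope."""

    latent: str
    entries: list[CurveEntry]
    scope: list[str]
    mc_standard_error: float = 0.0  # largest SE among Monte-Carlo prefixes

    def manifests(self) -> list[str]:
        return [e.manifest for e in self.entries]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["manifest\tpairwise_mi_bits\tcumulative_mi_bits\tcoverage_pct"]
        for e in self.entries:
            lines.append(
                f"{e.manifest}\t{e.pairwise_mi:.6f}\t{e.cumulative_mi:.6f}"
                f"\t{e.coverage:.2f}"
            )
        Path(path).write_text("\n".join(lines) + "\n", "utf-8")

    def plot(self, path: str | Path) -> None:
        """Two-curve layout: pairwise MI below, cumulative MI above, with a
        right-hand coverage axis."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        xs = np.arange(1, len(self.entries) + 1)
        pmi = [e.pairwise_mi for e in self.entries]
        cmi = [e.cumulative_mi for e in self.entries]
        cov = [e.coverage for e in self.entries]
        fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(xs)), 4))
        ax.plot(xs, cmi, "o-", color="tab:blue", label="cumulative MI")
        ax.plot(xs, pmi, "s--", color="tab:orange", label="pairwise MI")
        ax.set_ylabel("mutual information (bits)")
        ax.set_xticks(xs)
        ax.set_xticklabels(self.manifests(), rotation=75, ha="right", fontsize=7)
        ax2 = ax.twinx()
        ax2.plot(xs, cov, color="tab:green", alpha=0.4)
        ax2.axhline(95.0, color="grey", lw=0.8, ls=":")
        ax2.set_ylabel("information coverage (%)")
        ax2.set_ylim(0, 105)
        ax.set_title(f"information curve of {self.latent}")
        ax.legend(loc="center right", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def information_curve(
    model: LatentTreeModel,
    latent: str,
    scope: Sequence[str] | None = None,
    exact_limit: int = 2 ** 16,
    n_samples: int = 20000,
    seed: int = 0,
) -> InformationCurve:
    """Build the full information curve of ``latent`` over ``scope``.

    ``scope`` defaults to every manifest variable in the model. Entries are
    ordered by pairwise MI descending (ties broken alphabetically); coverage
    is normalised by the cumulative MI of the whole scope. Monte-Carlo
    prefixes share one seeded sample set, and the cumulative sequence is made
    non-decreasing by running maximum (exact prefixes are monotone already;
    only MC noise can dip).
    """
    if scope is None:
        scope = model.manifest_names
    scope = list(scope)
    if not scope:
        raise SchemaError("scope must be nonempty")
    if latent not in model.variables or model.variables[latent].kind != "latent":
        raise SchemaError(f"{latent!r} is not a latent variable of the model")

    pmis = {m: pairwise_mi(model, latent, m) for m in scope}
    order = sorted(scope, key=lambda m: (-pmis[m], m))

    samples = None
    max_k_exact = int(math.log2(exact_limit))
    if len(order) > max_k_exact:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        samples = sample_model(model, n_samples, rng)

    cum: list[float] = []
    worst_se = 0.0
    running = 0.0
    for k in range(1, len(order) + 1):
        prefix = order[:k]
        if k <= max_k_exact:
            val = _exact_joint_mi(model, latent, prefix)
        else:
            val, se = _mc_joint_mi(model, latent, prefix, samples)
            worst_se = max(worst_se, se)
        running = max(running, val)
        cum.append(running)

    total = cum[-1]
    if total <= 1e-12:
        raise DegenerateLatentError(
            f"latent {latent!r} carries no information about the scope"
        )
    entries = [
        CurveEntry(m, pmis[m], cum[i], 100.0 * cum[i] / total)
        for i, m in enumerate(order)
    ]
    return InformationCurve(latent, entries, scope, worst_se)


def select_significant(curve: InformationCurve, threshold: float = 95.0) -> list[str]:
    """Shortest curve prefix whose coverage reaches ``threshold`` percent.

    The prefix is never empty: with ``threshold=0`` the first entry alone is
    returned, and the final entry always has coverage 100 so a prefix exists.
    """
    for k, e in enumerate(curve.entries, start=1):
        if e.coverage >= threshold:
            return curve.manifests()[:k]
    return curve.manifests()
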