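"""Maximum-likelihood parameter estimation for a fixed tree via EM, plus BIC.

The E-step is exact sum-product on the tree; the M-step sets every CPT row to
the ratio of expected counts with a small additive pseudo-count (default 0.01
per cell) so sparse data cannot produce exact-zero cells. With the pseudo-count
the quantity EM monotonically increases is the lightly regularised (MAP)
objective ``loglik + smoothing * sum(log cpt_cells)``; that is what the
per-iteration trace records. The raw data log-likelihood of the final model is
reported separately and is what BIC uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import LatentTreeModel, loglikelihood, posteriors, PROB_FLOOR

__all__ = ["EMResult", "fit_em", "bic_score"]


@dataclass
class EMResult:
    model: LatentTreeModel
    loglik_trace: np.ndarray          # per-iteration maximized (MAP) objective
    converged: bool
    restarts_used: int
    seed: int
    loglik: float                     # raw data log-likelihood of final model
    n_iterations: int = 0
    objective: float = field(default=float("-inf"))  # final MAP objective

    def to_json_dict(self) -> dict:
        return {
            "model": self.model.to_json_dict(),
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "converged": bool(self.converged),
            "restarts_used": self.restarts_used,
            "seed": self.seed,
            "loglik": float(self.loglik),
            "n_iterations": self.n_iterations,
        }

    def save(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1), "utf-8")

    def trace_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["iteration\tobjective"]
        lines += [f"{i}\t{v!r}" for i, v in enumerate(self.loglik_trace)]
        Path(path).write_text("\n".join(lines) + "\n", "utf-8")


def _random_cpts(model: LatentTreeModel, rng: np.random.Generator) -> None:
    """In-place symmetric Dirichlet(1.0) re-initialisation of every CPT row."""
    for n in model.topo_order:
        t = model.cpts[n]
        if n == model.root:
            model.cpts[n] = rng.dirichlet(np.ones(t.shape[-1]))
        else:
            model.cpts[n] = rng.dirichlet(np.ones(t.shape[-1]), size=t.shape[0])


def _map_penalty(model: LatentTreeModel, smoothing: float) -> float:
    if smoothing <= 0:
        return 0.0
    return smoothing * sum(
        float(np.log(np.maximum(t, PROB_FLOOR)).sum()) for t in model.cpts.values()
    )


def fit_em(
    structure: LatentTreeModel,
    data,
    tol: float = 1e-6,
    max_iter: int = 500,
    restarts: int = 8,
    seed: int = 0,
    smoothing: float = 0.01,
    init_model: LatentTreeModel | None = None,
) -> EMResult:
    """Best-of-restarts EM fit of CPTs for a fixed tree structure.

    Parameters
    ----------
    structure : LatentTreeModel
        Defines the tree; its CPT values are ignored unless ``init_model``.
    data : SymptomMatrix / DataFrame / dict of 0-1 columns
        Must observe every manifest variable of the structure.
    tol : float
        Convergence threshold on the relative change of the objective.
    init_model : LatentTreeModel, optional
        Warm start used for the first restart (remaining restarts are random).
        With ``max_iter=0`` this evaluates the given parameters without moving
        them (trace of length 1).

    Notes
    -----
    Ties across restarts go to the lowest restart index, so results are
    deterministic given ``seed``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    observed = set(_columns_of(data))
    missing = [m for m in structure.manifest_names if m not in observed]
    if missing:
        raise ValueError(f"data does not observe manifest variables {missing}")

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(restarts)
    best: EMResult | None = None
    for r in range(restarts):
        rng = np.random.default_rng(streams[r])
        model = (init_model if (r == 0 and init_model is not None) else structure).copy()
        if not (r == 0 and init_model is not None):
            _random_cpts(model, rng)
        trace: list[float] = []
        converged = False
        it = 0
        while True:
            post, edge, ll_vec = posteriors(model, data)
            objective = float(ll_vec.sum()) + _map_penalty(model, smoothing)
            trace.append(objective)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (
                abs(trace[-2]) + 1.0
            ):
                converged = True
                break
            if it >= max_iter:
                break
            it += 1
            _m_step(model, data, post, edge, smoothing)
        result = EMResult(
            model=model,
            loglik_trace=np.array(trace),
            converged=converged,
            restarts_used=restarts,
            seed=seed,
            loglik=float("nan"),
            n_iterations=it,
            objective=trace[-1],
        )
        if best is None or result.objective > best.objective:
            best = result
    assert best is not None
    best.loglik = loglikelihood(best.model, data)
    return best


def _columns_of(data) -> Sequence[str]:
    if hasattr(data, "symptoms"):
        return data.symptoms
    if hasattr(data, "columns"):
        return [str(c) for c in data.columns]
    return list(data.keys())


def _m_step(model: LatentTreeModel, data, post, edge, smoothing: float) -> None:
    ev = _evidence_of(model, data)
    root = model.root
    counts = post[root].sum(axis=0) + smoothing
    model.cpts[root] = counts / counts.sum()
    for v in model.topo_order:
        if v == root:
            continue
        u = model.parent[v]
        if model.variables[v].kind == "latent":
            c = edge[v].sum(axis=0) + smoothing
        else:
            x = ev[v]
            c1 = post[u].T @ x  # (card_u,)
            c0 = post[u].sum(axis=0) - c1
            c = np.stack([c0, c1], axis=1) + smoothing
        model.cpts[v] = c / c.sum(axis=1, keepdims=True)


def _evidence_of(model: LatentTreeModel, data) -> dict[str, np.ndarray]:
    if hasattr(data, "evidence"):
        return data.evidence(model.manifest_names)
    if hasattr(data, "columns"):
        return {m: np.asarray(data[m], dtype=np.int64) for m in model.manifest_names}
    return {m: np.asarray(data[m], dtype=np.int64) for m in model.manifest_names}


def bic_score(model: LatentTreeModel, data, loglik: float | None = None) -> float:
    """BIC = loglik - (d/2) * ln N with d the number of free CPT parameters."""
    n = _n_records(data)
    if loglik is None:
        loglik = loglikelihood(model, data)
    return loglik - 0.5 * model.n_free_parameters() * np.log(n)


def _n_records(data) -> int:
    if hasattr(data, "n_records"):
        return data.n_records
    if hasattr(data, "shape"):
        return int(data.shape[0])
    return len(next(iter(data.values())))
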