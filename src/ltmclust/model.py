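"""Latent tree models over binary manifest variables, with exact inference.

A latent tree model (LTM, also "hierarchical latent class model") is a rooted
tree-structured Bayesian network: leaves are observed binary *manifest*
variables, internal nodes are unobserved discrete *latent* variables. The root
carries a marginal distribution; every other node carries a CPT of its states
given each parent state.

Inference is exact sum-product on the tree, vectorised over records. A
brute-force oracle (:func:`enumerate_joint`) materialises the full factored
joint tensor and is kept deliberately independent of the message-passing code
path so the two can check each other.

Log-likelihoods are in nats; mutual information helpers downstream report bits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import (
    CapacityError,
    ModelInvariantError,
    SchemaError,
    UndefinedPosteriorError,
)

__all__ = [
    "VariableSpec",
    "LatentTreeModel",
    "JointDistribution",
    "loglikelihood",
    "record_loglikelihoods",
    "posteriors",
    "posterior",
    "enumerate_joint",
    "pair_marginal",
    "sample_model",
    "latent_class_skeleton",
]

PROB_FLOOR = 1e-12  # guards log(0) from sampling-zero CPT cells
ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class VariableSpec:
    """A named model variable: manifest (binary leaf) or latent (internal)."""

    name: str
    kind: str  # "manifest" | "latent"
    cardinality: int = 2

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelInvariantError("variable name must be nonempty")
        if self.kind not in ("manifest", "latent"):
            raise ModelInvariantError(f"unknown variable kind {self.kind!r}")
        if self.cardinality < 2:
            raise ModelInvariantError(
                f"{self.name}: cardinality must be >= 2, got {self.cardinality}"
            )
        if self.kind == "manifest" and self.cardinality != 2:
            raise ModelInvariantError(
                f"manifest variable {self.name} must be binary"
            )


class LatentTreeModel:
    """Rooted tree of latent and manifest variables with CPTs.

    Parameters
    ----------
    variables : iterable of VariableSpec
    edges : iterable of (parent, child) name pairs forming a rooted tree
    cpts : mapping name -> array
        Root: shape (card,). Any other node: shape (parent_card, card),
        rows summing to 1.
    """

    def __init__(
        self,
        variables: Iterable[VariableSpec],
        edges: Iterable[tuple[str, str]],
        cpts: Mapping[str, np.ndarray],
    ) -> None:
        self.variables: dict[str, VariableSpec] = {}
        for v in variables:
            if v.name in self.variables:
                raise ModelInvariantError(f"duplicate variable name {v.name!r}")
            self.variables[v.name] = v

        self.parent: dict[str, str | None] = {n: None for n in self.variables}
        self.children: dict[str, list[str]] = {n: [] for n in self.variables}
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for p, c in edges:
            if p not in self.variables or c not in self.variables:
                raise ModelInvariantError(f"edge ({p!r}, {c!r}) names unknown variable")
            g.add_edge(p, c)
            self.parent[c] = p
            self.children[p].append(c)
        if len(self.variables) > 1 and not nx.is_arborescence(g):
            raise ModelInvariantError("edges do not form a single rooted tree")

        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ModelInvariantError(f"expected exactly one root, got {roots}")
        self.root = roots[0]
        if self.variables[self.root].kind != "latent":
            raise ModelInvariantError("root must be a latent variable")
        for n, spec in self.variables.items():
            if spec.kind == "manifest" and self.children[n]:
                raise ModelInvariantError(f"manifest variable {n} is not a leaf")

        self.cpts: dict[str, np.ndarray] = {}
        for n, spec in self.variables.items():
            if n not in cpts:
                raise ModelInvariantError(f"missing CPT for {n}")
            t = np.asarray(cpts[n], dtype=float)
            if n == self.root:
                want = (spec.cardinality,)
            else:
                want = (self.variables[self.parent[n]].cardinality, spec.cardinality)
            if t.shape != want:
                raise ModelInvariantError(
                    f"CPT for {n} has shape {t.shape}, expected {want}"
                )
            if (t < -ROW_SUM_TOL).any() or (t > 1 + ROW_SUM_TOL).any():
                raise ModelInvariantError(f"CPT for {n} has entries outside [0, 1]")
            sums = t.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=ROW_SUM_TOL):
                raise ModelInvariantError(f"CPT rows for {n} do not sum to 1")
            self.cpts[n] = t

        # parents before children
        self.topo_order: list[str] = list(nx.topological_sort(g)) if len(
            self.variables
        ) > 1 else [self.root]

    # -- views ------------------------------------------------------------

    @property
    def manifest_names(self) -> list[str]:
        return [n for n in self.topo_order if self.variables[n].kind == "manifest"]

    @property
    def latent_names(self) -> list[str]:
        return [n for n in self.topo_order if self.variables[n].kind == "latent"]

    def card(self, name: str) -> int:
        return self.variables[name].cardinality

    def edges(self) -> list[tuple[str, str]]:
        return [(self.parent[n], n) for n in self.topo_order if self.parent[n]]

    def leaf_descendants(self, name: str) -> list[str]:
        """Manifest leaves in the subtree rooted at ``name``."""
        out, stack = [], [name]
        while stack:
            n = stack.pop()
            if self.variables[n].kind == "manifest":
                out.append(n)
            stack.extend(reversed(self.children[n]))
        return out

    def copy(self) -> "LatentTreeModel":
        return LatentTreeModel(
            list(self.variables.values()),
            self.edges(),
            {n: t.copy() for n, t in self.cpts.items()},
        )

    def n_free_parameters(self) -> int:
        """Free CPT parameters: sum over nodes of (card-1) * card(parent)."""
        d = 0
        for n, spec in self.variables.items():
            pc = 1 if n == self.root else self.variables[self.parent[n]].cardinality
            d += (spec.cardinality - 1) * pc
        return d

    # -- serialization ----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "root": self.root,
            "nodes": [
                {"name": s.name, "kind": s.kind, "cardinality": s.cardinality}
                for s in (self.variables[n] for n in self.topo_order)
            ],
            "edges": [[p, c] for p, c in self.edges()],
            "cpts": {n: self.cpts[n].tolist() for n in self.topo_order},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1), "utf-8")

    @classmethod
    def from_json_dict(cls, d: dict) -> "LatentTreeModel":
        specs = [
            VariableSpec(n["name"], n["kind"], int(n["cardinality"]))
            for n in d["nodes"]
        ]
        return cls(specs, [tuple(e) for e in d["edges"]], d["cpts"])

    @classmethod
    def load(cls, path: str | Path) -> "LatentTreeModel":
        return cls.from_json_dict(json.loads(Path(path).read_text("utf-8")))

    def to_dot(self) -> str:
        """DOT export; edge line width is proportional to pairwise MI."""
        lines = ["digraph ltm {", "  rankdir=TB;"]
        for n in self.topo_order:
            spec = self.variables[n]
            if spec.kind == "latent":
                lines.append(
                    f'  "{n}" [shape=ellipse, label="{n} ({spec.cardinality})"];'
                )
            else:
                lines.append(f'  "{n}" [shape=box];')
        mis = {}
        for p, c in self.edges():
            mis[(p, c)] = mutual_information(pair_marginal(self, p, c))
        top = max(mis.values()) if mis else 1.0
        for (p, c), mi in mis.items():
            w = 0.5 + 4.5 * (mi / top if top > 0 else 0.0)
            lines.append(f'  "{p}" -> "{c}" [penwidth={w:.2f}, label="{mi:.3f}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass
class JointDistribution:
    """Exact probability table over an ordered subset of model variables."""

    variables: list[str]
    cards: list[int]
    table: np.ndarray  # shape == tuple(cards), sums to 1

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != tuple(self.cards):
            raise ModelInvariantError("joint table shape mismatch")
        if (self.table < -ROW_SUM_TOL).any():
            raise ModelInvariantError("joint table has negative entries")
        if abs(self.table.sum() - 1.0) > 1e-9:
            raise ModelInvariantError("joint table does not sum to 1")

    def marginal(self, subset: Sequence[str]) -> "JointDistribution":
        idx = [self.variables.index(v) for v in subset]
        other = tuple(i for i in range(len(self.variables)) if i not in idx)
        t = self.table.sum(axis=other)
        # after summing, remaining axes follow increasing original index;
        # permute them into the requested subset order
        remaining = sorted(idx)
        perm = [remaining.index(i) for i in idx]
        if t.ndim > 1:
            t = np.transpose(t, axes=perm)
        return JointDistribution(
            list(subset), [self.cards[self.variables.index(v)] for v in subset], t
        )


# ---------------------------------------------------------------------------
# message passing
# ---------------------------------------------------------------------------


def _as_evidence(model: LatentTreeModel, data) -> dict[str, np.ndarray]:
    """Normalise data (SymptomMatrix / DataFrame / dict of columns) to arrays."""
    if hasattr(data, "evidence"):
        ev = data.evidence()
    elif hasattr(data, "columns"):  # DataFrame
        ev = {str(c): np.asarray(data[c], dtype=np.int64) for c in data.columns}
    else:
        ev = {k: np.atleast_1d(np.asarray(v, dtype=np.int64)) for k, v in data.items()}
    for name in ev:
        if name not in model.variables:
            raise SchemaError(f"data column {name!r} is not a model variable")
        if model.variables[name].kind != "manifest":
            raise SchemaError(f"data column {name!r} is not a manifest variable")
    return ev


def _upward(model: LatentTreeModel, ev: dict[str, np.ndarray], floor: float = PROB_FLOOR):
    """Scaled upward (leaf-to-root) pass.

    Returns (beta, logw, msgs): per-latent scaled likelihood tables (N, card),
    per-latent per-record log scale factors, and per-child scaled messages
    to its parent (only for children that contributed evidence).
    """
    n_rec = len(next(iter(ev.values()))) if ev else 1
    beta: dict[str, np.ndarray] = {}
    logw: dict[str, np.ndarray] = {}
    msgs: dict[str, np.ndarray] = {}
    for v in reversed(model.topo_order):
        if model.variables[v].kind == "manifest":
            continue
        card = model.card(v)
        b = np.ones((n_rec, card))
        lw = np.zeros(n_rec)
        for c in model.children[v]:
            cspec = model.variables[c]
            cpt = np.maximum(model.cpts[c], floor)
            if cspec.kind == "manifest":
                if c not in ev:
                    continue  # unobserved leaf marginalises to 1
                m = cpt[:, ev[c]].T  # (N, card)
            else:
                m = beta[c] @ cpt.T
                lw = lw + logw[c]
            msgs[c] = m
            b = b * m
        s = b.max(axis=1)
        dead = s <= 0.0
        safe = np.where(dead, 1.0, s)
        b = b / safe[:, None]
        lw = lw + np.where(dead, -np.inf, np.log(safe))
        beta[v] = b
        logw[v] = lw
    return beta, logw, msgs


def record_loglikelihoods(model: LatentTreeModel, data, floor: float = PROB_FLOOR) -> np.ndarray:
    """Per-record log marginal probability of the observed configuration (nats)."""
    ev = _as_evidence(model, data)
    beta, logw, _ = _upward(model, ev, floor)
    root = model.root
    p = beta[root] @ np.maximum(model.cpts[root], floor)[: model.card(root)]
    with np.errstate(divide="ignore"):
        return np.log(p) + logw[root]


def loglikelihood(model: LatentTreeModel, data, floor: float = PROB_FLOOR) -> float:
    """Total data log-likelihood in nats (may be -inf for impossible records)."""
    return float(record_loglikelihoods(model, data, floor).sum())


def posteriors(model: LatentTreeModel, data, floor: float = PROB_FLOOR):
    """Exact per-record posteriors for every latent variable.

    Returns
    -------
    post : dict latent -> (N, card) array, P(latent | record)
    edge : dict latent v (non-root) -> (N, card_parent, card_v) array,
        P(parent(v), v | record)
    loglik : (N,) array of record log-likelihoods
    """
    ev = _as_evidence(model, data)
    beta, logw, msgs = _upward(model, ev, floor)
    root = model.root
    prior = np.maximum(model.cpts[root], floor)
    joint_root = beta[root] * prior[None, :]
    norm = joint_root.sum(axis=1)
    if (norm <= 0).any():
        raise UndefinedPosteriorError("evidence has probability zero under the model")
    post = {root: joint_root / norm[:, None]}
    edge: dict[str, np.ndarray] = {}
    with np.errstate(divide="ignore"):
        loglik = np.log(norm) + logw[root]
    for v in model.topo_order:
        if v == root or model.variables[v].kind == "manifest":
            continue
        u = model.parent[v]
        q = post[u] / np.maximum(msgs[v], 1e-300)
        cpt = np.maximum(model.cpts[v], floor)
        e = q[:, :, None] * cpt[None, :, :] * beta[v][:, None, :]
        e_sum = e.sum(axis=(1, 2), keepdims=True)
        e = e / np.maximum(e_sum, 1e-300)
        edge[v] = e
        post[v] = e.sum(axis=1)
    return post, edge, loglik


def posterior(model: LatentTreeModel, record: Mapping[str, int], latent: str) -> np.ndarray:
    """Posterior distribution of one latent given a (partial) manifest record."""
    if latent not in model.variables or model.variables[latent].kind != "latent":
        raise SchemaError(f"{latent!r} is not a latent variable of the model")
    ev = {k: np.array([v], dtype=np.int64) for k, v in record.items()}
    post, _, _ = posteriors(model, ev)
    return post[latent][0]


# ---------------------------------------------------------------------------
# brute-force oracle: full joint tensor (independent of message passing)
# ---------------------------------------------------------------------------


def full_joint(model: LatentTreeModel, limit: int = 2 ** 20) -> JointDistribution:
    """Exact joint over *all* variables as a dense tensor (testing oracle)."""
    order = model.topo_order
    cards = [model.card(n) for n in order]
    size = math.prod(cards)
    if size > limit:
        raise CapacityError(
            f"full joint has {size} cells > limit {limit}; "
            "use Monte-Carlo estimation instead"
        )
    axis = {n: i for i, n in enumerate(order)}
    table = np.ones(cards, dtype=float)
    for n in order:
        shape = [1] * len(order)
        if n == model.root:
            shape[axis[n]] = cards[axis[n]]
            table = table * model.cpts[n].reshape(shape)
        else:
            p = model.parent[n]
            shape[axis[p]] = model.card(p)
            shape[axis[n]] = model.card(n)
            table = table * model.cpts[n].reshape(shape)
    return JointDistribution(list(order), cards, table)


def enumerate_joint(
    model: LatentTreeModel, subset: Sequence[str], limit: int = 2 ** 20
) -> JointDistribution:
    """Exact marginal over ``subset`` by summing the full factored joint."""
    for v in subset:
        if v not in model.variables:
            raise SchemaError(f"unknown variable {v!r}")
    joint = full_joint(model, limit)
    keep = [joint.variables.index(v) for v in subset]
    other = tuple(i for i in range(len(joint.variables)) if i not in keep)
    t = joint.table.sum(axis=other)
    # axes of t follow increasing original index; permute to subset order
    remaining = sorted(keep)
    perm = [remaining.index(i) for i in keep]
    t = np.transpose(t, axes=perm) if t.ndim > 1 else t
    return JointDistribution(list(subset), [model.card(v) for v in subset], t)


# ---------------------------------------------------------------------------
# pairwise marginals along the tree (exact, no enumeration)
# ---------------------------------------------------------------------------


def node_marginals(model: LatentTreeModel) -> dict[str, np.ndarray]:
    """Unconditional marginal of every variable, by root-to-leaf propagation."""
    marg = {model.root: model.cpts[model.root].copy()}
    for n in model.topo_order:
        if n == model.root:
            continue
        marg[n] = marg[model.parent[n]] @ model.cpts[n]
    return marg


def _chain_matrix(model: LatentTreeModel, ancestor: str, descendant: str) -> np.ndarray:
    """P(descendant | ancestor) as a (card_a, card_d) matrix along the path."""
    path = [descendant]
    n = descendant
    while n != ancestor:
        n = model.parent[n]
        if n is None:
            raise SchemaError(f"{ancestor!r} is not an ancestor of {descendant!r}")
        path.append(n)
    path.reverse()  # ancestor ... descendant
    m = np.eye(model.card(ancestor))
    for nxt in path[1:]:
        m = m @ model.cpts[nxt]
    return m


def _depth(model: LatentTreeModel, n: str) -> int:
    d = 0
    while model.parent[n] is not None:
        n = model.parent[n]
        d += 1
    return d


def pair_marginal(model: LatentTreeModel, a: str, b: str) -> JointDistribution:
    """Exact joint P(a, b) for any two distinct variables of the model."""
    if a == b:
        raise SchemaError("pair_marginal needs two distinct variables")
    # find lowest common ancestor by walking up
    anc_a, n = {a}, a
    while model.parent[n] is not None:
        n = model.parent[n]
        anc_a.add(n)
    w = b
    while w not in anc_a:
        w = model.parent[w]
    marg = node_marginals(model)
    if w == a:
        t = marg[a][:, None] * _chain_matrix(model, a, b)
    elif w == b:
        t = (marg[b][:, None] * _chain_matrix(model, b, a)).T
    else:
        ma = _chain_matrix(model, w, a)  # (card_w, card_a)
        mb = _chain_matrix(model, w, b)
        t = np.einsum("w,wa,wb->ab", marg[w], ma, mb)
    return JointDistribution([a, b], [model.card(a), model.card(b)], t)


def mutual_information(joint: JointDistribution, base: float = 2.0) -> float:
    """MI of a two-variable joint distribution (bits by default)."""
    t = joint.table
    if t.ndim != 2:
        raise SchemaError("mutual_information expects a two-variable joint")
    pa = t.sum(axis=1, keepdims=True)
    pb = t.sum(axis=0, keepdims=True)
    mask = t > 0
    ratio = np.where(mask, t / np.maximum(pa * pb, 1e-300), 1.0)
    mi = float((t[mask] * np.log(ratio[mask])).sum() / math.log(base))
    return max(mi, 0.0)


# ---------------------------------------------------------------------------
# sampling and construction helpers
# ---------------------------------------------------------------------------


def sample_model(
    model: LatentTreeModel, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Ancestral sampling: n i.i.d. joint configurations of every variable."""
    if n < 1:
        raise ValueError("need n >= 1 samples")
    out: dict[str, np.ndarray] = {}
    for v in model.topo_order:
        card = model.card(v)
        if v == model.root:
            out[v] = rng.choice(card, size=n, p=model.cpts[v])
        else:
            p = model.cpts[v][out[model.parent[v]]]
            u = rng.random(n)
            out[v] = (u[:, None] >= p.cumsum(axis=1)).sum(axis=1)
    return out


def latent_class_skeleton(
    columns: Sequence[str], cardinality: int = 2, latent_name: str = "Z"
) -> LatentTreeModel:
    """Flat latent class model: one latent root over the given manifest leaves.

    CPTs are uniform placeholders; callers re-fit by EM.
    """
    specs = [VariableSpec(latent_name, "latent", cardinality)] + [
        VariableSpec(c, "manifest", 2) for c in columns
    ]
    edges = [(latent_name, c) for c in columns]
    cpts: dict[str, np.ndarray] = {
        latent_name: np.full(cardinality, 1.0 / cardinality)
    }
    for c in columns:
        cpts[c] = np.full((cardinality, 2), 0.5)
    return LatentTreeModel(specs, edges, cpts)
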