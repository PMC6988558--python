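"""Discrete Bayesian networks: naive and tree-augmented structure, CPT
learning from case files, exact inference, and complexity accounting.

The model family is deliberately small.  A *naive* network has links from
the response (class) node to every covariate.  A *tree-augmented* (TAN)
network additionally connects the covariates by a spanning tree chosen to
maximize total class-conditional mutual information (the Chow–Liu tree of
the covariates given the class), so each covariate has at most two parents:
the response, plus at most one other covariate.  For k >= 2 covariates a
TAN therefore has exactly 2k - 1 directed links.

Conditional probability tables are learned by counting state frequencies
in the case file with Laplace-style smoothing (``alpha`` pseudo-counts per
cell; ``alpha=0`` gives pure empirical frequencies).  Inference over the
class is exact: observed covariates enter as likelihood factors and missing
covariates are summed out along the covariate tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .discretize import DiscretizedCases


class ComplexityTriple(NamedTuple):
    """Node, link, and probability-value counts of a network."""

    n_nodes: int
    n_links: int
    n_probabilities: int


@dataclass
class BNModel:
    """A naive/TAN classifier over discretized covariates.

    ``tree_parent`` maps each covariate to its covariate parent (or None);
    the response is implicitly a parent of every covariate.  CPT layout:
    ``prior`` has shape (C,); a covariate without tree parent has a CPT of
    shape (C, S); with tree parent P, shape (C, |P|, S).  Every CPT row
    sums to 1.
    """

    response: str
    response_states: tuple
    nodes: dict  # covariate name -> ordered state tuple
    tree_parent: dict  # covariate name -> covariate name | None
    prior: np.ndarray | None = None
    cpts: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for x, p in self.tree_parent.items():
            if x not in self.nodes or (p is not None and p not in self.nodes):
                raise ValueError(f"tree link {p}->{x} references unknown node")
        # Acyclicity of the covariate forest: following parents must terminate.
        for x in self.nodes:
            seen = set()
            while x is not None:
                if x in seen:
                    raise ValueError("covariate links contain a cycle")
                seen.add(x)
                x = self.tree_parent.get(x)

    @property
    def covariates(self) -> list:
        return list(self.nodes)

    @property
    def links(self) -> list:
        """Directed links, response->covariate first, then tree links."""
        out = [(self.response, x) for x in self.nodes]
        out += [(p, x) for x, p in self.tree_parent.items() if p is not None]
        return out

    def children(self) -> dict:
        ch = {x: [] for x in self.nodes}
        for x, p in self.tree_parent.items():
            if p is not None:
                ch[p].append(x)
        return ch

    def is_fitted(self) -> bool:
        return self.prior is not None and set(self.cpts) == set(self.nodes)


def conditional_mutual_information(dcases: DiscretizedCases, xi: str, xj: str,
                                   c: str | None = None) -> float:
    """Empirical I(Xi; Xj | C) in bits over cases complete in all three.

    Zero-probability terms contribute zero.  Raises if no complete case.
    """
    c = c or dcases.response_col
    a, b, cc = dcases.column(xi), dcases.column(xj), dcases.column(c)
    mask = (a >= 0) & (b >= 0) & (cc >= 0)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no cases complete in ({xi}, {xj}, {c})")
    si, sj, sc = (len(dcases.states[v]) for v in (xi, xj, c))
    flat = (cc[mask].astype(np.int64) * si + a[mask]) * sj + b[mask]
    p = np.bincount(flat, minlength=sc * si * sj).reshape(sc, si, sj) / n
    pc = p.sum(axis=(1, 2), keepdims=True)
    pic = p.sum(axis=2, keepdims=True)
    pjc = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p * pc / (pic * pjc))
    return float(np.nansum(term))


def _kruskal_max_tree(nodes: list, weights: dict) -> list:
    """Maximum-weight spanning tree; ties broken by lexicographic edge name."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    edges = sorted(weights, key=lambda e: (-weights[e], e))
    chosen = []
    for (u, v) in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v))
    return chosen


def learn_tan_structure(dcases: DiscretizedCases, covariates: list,
                        response: str | None = None,
                        root: str | None = None) -> BNModel:
    """Induce a TAN (or naive, for one covariate) skeleton from cases.

    Edge weights are class-conditional mutual information; the maximum
    spanning tree over the covariates is oriented outward from ``root``
    (default: the first covariate in the given order).  Deterministic:
    MST ties break lexicographically.
    """
    response = response or dcases.response_col
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    unknown = [x for x in covariates if x not in dcases.states]
    if unknown:
        raise ValueError(f"covariates not in case table: {unknown}")
    root = root or covariates[0]
    tree_parent = {x: None for x in covariates}
    if len(covariates) >= 2:
        weights = {}
        for i, u in enumerate(covariates):
            for v in covariates[i + 1:]:
                key = (u, v) if u <= v else (v, u)
                weights[key] = conditional_mutual_information(dcases, u, v, response)
        undirected = _kruskal_max_tree(sorted(covariates), weights)
        adj = {x: [] for x in covariates}
        for u, v in undirected:
            adj[u].append(v)
            adj[v].append(u)
        # Orient outward from the root by BFS.
        queue, seen = [root], {root}
        while queue:
            u = queue.pop(0)
            for v in sorted(adj[u]):
                if v not in seen:
                    tree_parent[v] = u
                    seen.add(v)
                    queue.append(v)
    return BNModel(
        response=response,
        response_states=tuple(dcases.states[response]),
        nodes={x: tuple(dcases.states[x]) for x in covariates},
        tree_parent=tree_parent,
        metadata={"root": root},
    )


def learn_naive_structure(dcases: DiscretizedCases, covariates: list,
                          response: str | None = None) -> BNModel:
    """Naive-Bayes skeleton: response is the sole parent of each covariate."""
    response = response or dcases.response_col
    return BNModel(
        response=response,
        response_states=tuple(dcases.states[response]),
        nodes={x: tuple(dcases.states[x]) for x in covariates},
        tree_parent={x: None for x in covariates},
    )


def learn_cpts(model: BNModel, dcases: DiscretizedCases, alpha: float = 1.0) -> BNModel:
    """Fill the model's CPTs from state frequencies in the case file.

    Each row is (count + alpha) / (total + alpha * |states|); counts for a
    node use the cases complete in that node and all its parents
    (available-case analysis).  With ``alpha=0``, never-observed parent
    configurations get a uniform row.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    C = len(model.response_states)
    c = dcases.column(model.response)
    cmask = c >= 0
    ccounts = np.bincount(c[cmask], minlength=C).astype(float)
    tot = ccounts.sum() + alpha * C
    model.prior = ((ccounts + alpha) / tot) if tot > 0 else np.full(C, 1.0 / C)

    for x in model.nodes:
        S = len(model.nodes[x])
        xs = dcases.column(x)
        p = model.tree_parent[x]
        if p is None:
            mask = cmask & (xs >= 0)
            flat = c[mask].astype(np.int64) * S + xs[mask]
            counts = np.bincount(flat, minlength=C * S).reshape(C, S).astype(float)
        else:
            P = len(model.nodes[p])
            ps = dcases.column(p)
            mask = cmask & (xs >= 0) & (ps >= 0)
            flat = (c[mask].astype(np.int64) * P + ps[mask]) * S + xs[mask]
            counts = np.bincount(flat, minlength=C * P * S).reshape(C, P, S).astype(float)
        totals = counts.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cpt = (counts + alpha) / (totals + alpha * S)
        uniform_rows = (totals[..., 0] + alpha * S) == 0
        if uniform_rows.any():
            cpt[uniform_rows] = 1.0 / S
        model.cpts[x] = cpt
    return model


def _encode_evidence(model: BNModel, evidence: dict) -> dict:
    codes = {}
    for name, state in evidence.items():
        if state is None:
            continue
        if name not in model.nodes:
            raise ValueError(f"evidence on unknown node {name!r}")
        if isinstance(state, str):
            try:
                codes[name] = model.nodes[name].index(state)
            except ValueError:
                raise ValueError(f"unknown state {state!r} for node {name!r}") from None
        else:
            code = int(state)
            if not 0 <= code < len(model.nodes[name]):
                raise ValueError(f"state code {code} out of range for node {name!r}")
            codes[name] = code
    return codes


def _class_likelihood(model: BNModel, codes: dict) -> np.ndarray:
    """P(evidence | C=c) for each class, missing covariates summed out.

    Upward message passing on the covariate forest: the message of a node
    to its tree parent, per class and parent state, sums the node's CPT row
    over its allowed states times its children's messages.
    """
    children = model.children()
    C = len(model.response_states)

    def msg(x: str) -> np.ndarray:  # shape (C, S_x): factor per own state
        cpt = model.cpts[x]  # (C, S) or (C, P, S)
        own = np.ones((C, cpt.shape[-1]))
        for ch in children[x]:
            own *= msg_to_parent(ch)  # (C, S_x)
        if x in codes:
            keep = np.zeros(cpt.shape[-1])
            keep[codes[x]] = 1.0
            own = own * keep
        return own

    def msg_to_parent(x: str) -> np.ndarray:  # shape (C, S_parent)
        cpt = model.cpts[x]  # (C, P, S)
        own = msg(x)  # (C, S)
        return np.einsum("cps,cs->cp", cpt, own)

    lik = np.ones(C)
    for x in model.nodes:
        if model.tree_parent[x] is None:
            cpt = model.cpts[x]  # (C, S)
            lik = lik * np.einsum("cs,cs->c", cpt, msg(x))
    return lik


def posterior(model: BNModel, evidence: dict | None = None) -> np.ndarray:
    """Posterior P(C | evidence) over the response states.

    ``evidence`` maps covariate name to a state label (or index); missing
    covariates (absent or None) are marginalized exactly.  With no evidence
    the result is the response prior.
    """
    if not model.is_fitted():
        raise ValueError("model has no learned CPTs")
    codes = _encode_evidence(model, evidence or {})
    joint = model.prior * _class_likelihood(model, codes)
    z = joint.sum()
    if z <= 0:
        return np.full(len(model.response_states), 1.0 / len(model.response_states))
    return joint / z


def predict(model: BNModel, evidence: dict | None = None) -> str:
    """Most probable response state; ties go to the earlier-listed state."""
    post = posterior(model, evidence)
    return model.response_states[int(np.argmax(post))]


def posterior_batch(model: BNModel, dcases: DiscretizedCases) -> np.ndarray:
    """Posterior for every case in a discretized table, shape (n, C).

    Fully-observed rows take a vectorized product-of-factors path; rows
    with missing covariates fall back to exact per-row marginalization.
    """
    if not model.is_fitted():
        raise ValueError("model has no learned CPTs")
    cols = {x: dcases.column(x) for x in model.nodes}
    n = len(dcases)
    C = len(model.response_states)
    if model.nodes:
        observed = np.all(np.stack([cols[x] >= 0 for x in model.nodes]), axis=0)
    else:
        observed = np.ones(n, dtype=bool)
    out = np.empty((n, C))

    if observed.any():
        joint = np.tile(model.prior, (int(observed.sum()), 1))
        for x in model.nodes:
            cpt = model.cpts[x]
            xv = cols[x][observed]
            p = model.tree_parent[x]
            if p is None:
                joint *= cpt[:, xv].T  # (n_obs, C)
            else:
                pv = cols[p][observed]
                joint *= cpt[:, pv, xv].T
        z = joint.sum(axis=1, keepdims=True)
        safe = z[:, 0] > 0
        joint[safe] /= z[safe]
        joint[~safe] = 1.0 / C
        out[observed] = joint

    for i in np.flatnonzero(~observed):
        codes = {x: int(cols[x][i]) for x in model.nodes if cols[x][i] >= 0}
        joint = model.prior * _class_likelihood(model, codes)
        z = joint.sum()
        out[i] = joint / z if z > 0 else np.full(C, 1.0 / C)
    return out


def complexity(model: BNModel) -> ComplexityTriple:
    """Node, link, and probability-value counts (all CPT cells, prior included)."""
    n_nodes = 1 + len(model.nodes)
    n_links = len(model.links)
    n_probs = len(model.response_states)
    for x, states in model.nodes.items():
        size = len(model.response_states) * len(states)
        p = model.tree_parent[x]
        if p is not None:
            size *= len(model.nodes[p])
        n_probs += size
    return ComplexityTriple(n_nodes, n_links, n_probs)


def model_to_json(model: BNModel, path=None) -> str:
    """Serialize a model (structure + CPTs) to JSON; round-trip exact."""
    doc = {
        "response": model.response,
        "response_states": list(model.response_states),
        "nodes": {x: list(s) for x, s in model.nodes.items()},
        "tree_parent": model.tree_parent,
        "prior": None if model.prior is None else model.prior.tolist(),
        "cpts": {x: cpt.tolist() for x, cpt in model.cpts.items()},
        "metadata": model.metadata,
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def model_from_json(source) -> BNModel:
    """Inverse of :func:`model_to_json`; accepts a JSON string or a path."""
    text = str(source)
    if not text.lstrip().startswith("{"):
        with open(source) as fh:
            text = fh.read()
    doc = json.loads(text)
    return BNModel(
        response=doc["response"],
        response_states=tuple(doc["response_states"]),
        nodes={x: tuple(s) for x, s in doc["nodes"].items()},
        tree_parent=dict(doc["tree_parent"]),
        prior=None if doc["prior"] is None else np.asarray(doc["prior"]),
        cpts={x: np.asarray(c) for x, c in doc["cpts"].items()},
        metadata=doc.get("metadata", {}),
    )
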