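"""Linear structural-equation path models over observed variables.

A :class:`PathModel` is a directed system of linear equations among observed
variables: structural edges (free or fixed coefficients), exogenous
variances/covariances and residual variances of endogenous variables.  With
B the coefficient matrix (B[i, j] the effect of variable j on variable i)
and Psi the exogenous/residual covariance, the model-implied covariance is

    Sigma(theta) = (I - B)^{-1} Psi (I - B)^{-T}

Parameters follow lavaan-style names: ``"y~x"`` for a path, ``"a~~b"`` for a
(co)variance.  The structural graph must be acyclic (recursive or otherwise
non-cyclic systems only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Edge", "Covariance", "PathModel", "model_df", "implied_covariance"]


@dataclass(frozen=True)
class Edge:
    """Directed structural path src -> dst; free or fixed at ``value``."""

    src: str
    dst: str
    free: bool = True
    value: float = 0.0

    @property
    def name(self) -> str:
        return f"{self.dst}~{self.src}"


@dataclass(frozen=True)
class Covariance:
    """(Co)variance parameter; a == b denotes a variance."""

    a: str
    b: str
    free: bool = True
    value: float = 0.0

    @property
    def name(self) -> str:
        return f"{self.a}~~{self.b}"


@dataclass(frozen=True)
class PathModel:
    variables: tuple
    edges: tuple
    covariances: tuple = field(default=None)

    def __post_init__(self):
        variables = tuple(self.variables)
        if len(set(variables)) != len(variables):
            raise ValueError("duplicate variable names")
        edges = tuple(self.edges)
        for e in edges:
            if e.src not in variables or e.dst not in variables:
                raise ValueError(f"edge {e.name} references unknown variable")
            if e.src == e.dst:
                raise ValueError(f"self-loop {e.name}")
        if len({(e.src, e.dst) for e in edges}) != len(edges):
            raise ValueError("duplicate edges")
        object.__setattr__(self, "variables", variables)
        object.__setattr__(self, "edges", edges)

        # acyclicity of the structural part (topological sort)
        children: dict = {v: [] for v in variables}
        indeg = {v: 0 for v in variables}
        for e in edges:
            children[e.src].append(e.dst)
            indeg[e.dst] += 1
        queue = [v for v in variables if indeg[v] == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(variables):
            raise ValueError("structural graph contains a cycle")

        if self.covariances is None:
            object.__setattr__(self, "covariances", self._default_covariances())
        else:
            covs = tuple(self.covariances)
            keys = set()
            for c in covs:
                if c.a not in variables or c.b not in variables:
                    raise ValueError(f"covariance {c.name} references unknown variable")
                key = frozenset((c.a, c.b))
                if key in keys:
                    raise ValueError(f"duplicate covariance {c.name}")
                keys.add(key)
            for v in variables:
                if frozenset((v, v)) not in keys:
                    raise ValueError(f"no variance parameter declared for {v!r}")
            object.__setattr__(self, "covariances", covs)

        if self.n_free > self.n_moments:
            raise ValueError("model has more free parameters than sample moments")

    # -- construction helpers ------------------------------------------------

    def _default_covariances(self) -> tuple:
        """Free variances for every variable; free covariances among
        exogenous variables; endogenous residual covariances fixed at 0
        (omitted)."""
        exo = self.exogenous
        covs = [Covariance(v, v, free=True) for v in self.variables]
        for i, a in enumerate(exo):
            for b in exo[i + 1 :]:
                covs.append(Covariance(a, b, free=True))
        return tuple(covs)

    @classmethod
    def from_dict(cls, spec: dict) -> "PathModel":
        """Build from the mapping layout used by the YAML/JSON model files.

        ``{"variables": [...], "edges": [[src, dst], [src, dst, value], ...],
        "covariances": [[a, b], [a, b, value], ...]}`` — a third element
        fixes the parameter at that value, otherwise it is free.
        """
        variables = tuple(spec["variables"])
        edges = tuple(
            Edge(e[0], e[1], free=len(e) < 3, value=float(e[2]) if len(e) > 2 else 0.0)
            for e in spec["edges"]
        )
        covs = None
        if "covariances" in spec and spec["covariances"] is not None:
            covs = tuple(
                Covariance(
                    c[0], c[1], free=len(c) < 3, value=float(c[2]) if len(c) > 2 else 0.0
                )
                for c in spec["covariances"]
            )
        return cls(variables, edges, covs)

    # -- bookkeeping ---------------------------------------------------------

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def n_moments(self) -> int:
        return self.p * (self.p + 1) // 2

    @property
    def exogenous(self) -> tuple:
        with_parents = {e.dst for e in self.edges}
        return tuple(v for v in self.variables if v not in with_parents)

    @property
    def endogenous(self) -> tuple:
        with_parents = {e.dst for e in self.edges}
        return tuple(v for v in self.variables if v in with_parents)

    @property
    def free_names(self) -> tuple:
        return tuple(
            [e.name for e in self.edges if e.free]
            + [c.name for c in self.covariances if c.free]
        )

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def index(self, variable: str) -> int:
        return self.variables.index(variable)

    def parents(self, variable: str) -> tuple:
        return tuple(e.src for e in self.edges if e.dst == variable)

    def matrices(self, params: dict) -> tuple:
        """(B, Psi) for a complete parameter assignment.

        ``params`` maps free-parameter names to values; fixed parameters use
        their declared values.  Missing free parameters raise.
        """
        missing = [n for n in self.free_names if n not in params]
        if missing:
            raise ValueError(f"missing value(s) for free parameter(s) {missing}")
        p = self.p
        B = np.zeros((p, p))
        for e in self.edges:
            val = params[e.name] if e.free else e.value
            B[self.index(e.dst), self.index(e.src)] = val
        Psi = np.zeros((p, p))
        for c in self.covariances:
            val = params[c.name] if c.free else c.value
            i, j = self.index(c.a), self.index(c.b)
            Psi[i, j] = Psi[j, i] = val
        return B, Psi


def model_df(model: PathModel) -> int:
    """Degrees of freedom: observed moments p(p+1)/2 minus free parameters."""
    df = model.n_moments - model.n_free
    if df < 0:
        raise ValueError("model is over-parameterized (negative df)")
    return df


def implied_covariance(model: PathModel, params: dict) -> np.ndarray:
    """Model-implied covariance Sigma = (I-B)^{-1} Psi (I-B)^{-T}."""
    B, Psi = model.matrices(params)
    I = np.eye(model.p)
    IB = I - B
    if abs(np.linalg.det(IB)) < 1e-12:
        raise ValueError("I - B is singular")
    A = np.linalg.inv(IB)
    return A @ Psi @ A.T
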