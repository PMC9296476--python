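"""Mediation decomposition of fitted path models.

For linear path models the total effect of a source on an outcome is the
sum over all directed paths of the product of coefficients along each path.
The indirect effect *through a given mediator* is the part of the total
carried by paths that pass through the mediator; it equals the difference
between the total effect and the total effect with the mediator's outgoing
edges severed.  For the classic one-mediator triangle this reduces to the
product-of-coefficients a*b.

Two proportion-mediated conventions are reported, because published
analyses differ on whether "total" includes routes through other mediators:

* ``proportion_mediated`` = 100 * indirect / (indirect + direct), with
  ``direct`` the single direct edge source -> outcome;
* ``proportion_of_total`` = 100 * indirect / total, with ``total`` the full
  total effect (all routes).

When indirect and direct disagree in sign the first proportion is not
interpretable; it is returned as NaN with ``same_signed = False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fit import SemFit
from .model import PathModel

__all__ = ["MediationResult", "mediation_effects", "total_effect_matrix"]


def total_effect_matrix(B: np.ndarray) -> np.ndarray:
    """Total effects (I - B)^{-1} - I; entry [i, j] is the effect of j on i."""
    p = B.shape[0]
    return np.linalg.inv(np.eye(p) - B) - np.eye(p)


@dataclass
class MediationResult:
    source: str
    mediator: str
    outcome: str
    indirect: float
    direct: float
    total: float
    proportion_mediated: float
    proportion_of_total: float
    same_signed: bool


def _has_directed_path(model: PathModel, src: str, dst: str) -> bool:
    children = {v: [] for v in model.variables}
    for e in model.edges:
        children[e.src].append(e.dst)
    stack, seen = [src], set()
    while stack:
        v = stack.pop()
        if v == dst:
            return True
        for c in children[v]:
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return False


def mediation_effects(
    fit: SemFit, source: str, mediator: str, outcome: str
) -> MediationResult:
    """Decompose the effect of ``source`` on ``outcome`` through ``mediator``.

    Requires directed paths source -> mediator and mediator -> outcome in the
    structural graph; a direct source -> outcome edge is optional (its
    absence means a direct effect of exactly 0).
    """
    model = fit.model
    for v in (source, mediator, outcome):
        if v not in model.variables:
            raise ValueError(f"unknown variable {v!r}")
    if not _has_directed_path(model, source, mediator):
        raise ValueError(f"no directed path {source} -> {mediator}")
    if not _has_directed_path(model, mediator, outcome):
        raise ValueError(f"no directed path {mediator} -> {outcome}")

    B, _ = model.matrices(fit.estimates)
    idx = model.index
    T_full = total_effect_matrix(B)
    B_cut = B.copy()
    B_cut[:, idx(mediator)] = 0.0      # sever the mediator's outgoing edges
    T_cut = total_effect_matrix(B_cut)

    total = float(T_full[idx(outcome), idx(source)])
    indirect = float(total - T_cut[idx(outcome), idx(source)])
    direct = float(B[idx(outcome), idx(source)])

    same_signed = indirect == 0.0 or direct == 0.0 or (indirect * direct > 0)
    if indirect == 0.0:
        prop = 0.0
    elif same_signed:
        prop = 100.0 * indirect / (indirect + direct)
    else:
        prop = np.nan
    prop_total = 100.0 * indirect / total if total != 0 else np.nan
    return MediationResult(
        source=source,
        mediator=mediator,
        outcome=outcome,
        indirect=indirect,
        direct=direct,
        total=total,
        proportion_mediated=float(prop),
        proportion_of_total=float(prop_total),
        same_signed=same_signed,
    )
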