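"""The five competing causal constructs over the cohort biomarkers.

All models share one observed-variable set: amyloid PET, tau PET, HDAC PET,
atrophy (grey-matter density), cognition (MMSE-like), plus age, sex and
education.  Atrophy and cognition are recorded so that lower = worse; HDAC
paths are therefore positive and pathology paths negative in the
mediation-generating regime.  Each construct orders the biomarkers
differently:

1. ``hdac_mediation_model``     — HDAC reduction mediates amyloid and tau
   effects on atrophy and cognition (the hypothesis construct; 6 df).
2. ``hdac_after_atrophy_model`` — HDAC reduction is downstream of atrophy
   (no direct pathology -> HDAC paths).
3. ``hdac_first_model``         — HDAC reduction precedes amyloid and tau
   and reaches the outcomes only through them.
4. ``hdac_between_model``       — HDAC succeeds amyloid and precedes tau;
   its whole downstream influence flows through tau.
5. ``classical_cascade_model``  — the classical amyloid -> tau -> atrophy ->
   cognition sequence with HDAC structurally disconnected.

The alternatives are deliberately restrictive — each drops direct paths the
ordering forbids — so they are distinguishable from the hypothesis
construct (a set of complete biomarker orderings would be Markov equivalent
and fit identically).  Every construct keeps the three covariates pointing
at both outcomes and frees all exogenous variances/covariances.
"""

from __future__ import annotations

from .model import Covariance, Edge, PathModel

__all__ = [
    "COHORT_VARIABLES",
    "hdac_mediation_model",
    "hdac_after_atrophy_model",
    "hdac_first_model",
    "hdac_between_model",
    "classical_cascade_model",
    "five_model_suite",
    "mediation_true_params",
]

COHORT_VARIABLES = (
    "amyloid",
    "tau",
    "hdac",
    "atrophy",
    "cognition",
    "age",
    "sex",
    "education",
)

_COVARIATE_EDGES = [
    Edge("age", "atrophy"),
    Edge("sex", "atrophy"),
    Edge("education", "atrophy"),
    Edge("age", "cognition"),
    Edge("sex", "cognition"),
    Edge("education", "cognition"),
]


def _build(biomarker_edges, extra_covariances=None):
    return PathModel(
        COHORT_VARIABLES,
        tuple(biomarker_edges) + tuple(_COVARIATE_EDGES),
        covariances=extra_covariances,
    )


def hdac_mediation_model() -> PathModel:
    """Construct 1: amyloid -> tau -> HDAC -> {atrophy, cognition}."""
    return _build(
        [
            Edge("amyloid", "tau"),
            Edge("amyloid", "hdac"),
            Edge("tau", "hdac"),
            Edge("amyloid", "atrophy"),
            Edge("tau", "atrophy"),
            Edge("hdac", "atrophy"),
            Edge("amyloid", "cognition"),
            Edge("tau", "cognition"),
            Edge("hdac", "cognition"),
            Edge("atrophy", "cognition"),
        ]
    )


def hdac_after_atrophy_model() -> PathModel:
    """Construct 2: HDAC reduction is a consequence of atrophy.

    The pathologies drive atrophy directly; HDAC depends on atrophy alone,
    so any tau- or amyloid-specific HDAC association must be carried through
    atrophy.
    """
    return _build(
        [
            Edge("amyloid", "tau"),
            Edge("amyloid", "atrophy"),
            Edge("tau", "atrophy"),
            Edge("atrophy", "hdac"),
            Edge("amyloid", "cognition"),
            Edge("tau", "cognition"),
            Edge("atrophy", "cognition"),
            Edge("hdac", "cognition"),
        ]
    )


def hdac_first_model() -> PathModel:
    """Construct 3: HDAC reduction precedes amyloid and tau pathologies.

    HDAC is exogenous and influences atrophy and cognition only through the
    pathologies it triggers.
    """
    return _build(
        [
            Edge("hdac", "amyloid"),
            Edge("hdac", "tau"),
            Edge("amyloid", "tau"),
            Edge("amyloid", "atrophy"),
            Edge("tau", "atrophy"),
            Edge("amyloid", "cognition"),
            Edge("tau", "cognition"),
            Edge("atrophy", "cognition"),
        ]
    )


def hdac_between_model() -> PathModel:
    """Construct 4: HDAC succeeds amyloid and precedes tau.

    Amyloid lowers HDAC, which drives tau; downstream damage is carried by
    amyloid and tau only.
    """
    return _build(
        [
            Edge("amyloid", "hdac"),
            Edge("hdac", "tau"),
            Edge("amyloid", "atrophy"),
            Edge("tau", "atrophy"),
            Edge("amyloid", "cognition"),
            Edge("tau", "cognition"),
            Edge("atrophy", "cognition"),
        ]
    )


def classical_cascade_model() -> PathModel:
    """Construct 5: amyloid -> tau -> atrophy -> cognition without HDAC.

    HDAC stays in the variable set (comparison requires a common set) as an
    exogenous variable correlated only with the other exogenous variables;
    its association with the cascade is deliberately unmodelled.
    """
    edges = [
        Edge("amyloid", "tau"),
        Edge("amyloid", "atrophy"),
        Edge("tau", "atrophy"),
        Edge("amyloid", "cognition"),
        Edge("tau", "cognition"),
        Edge("atrophy", "cognition"),
    ] + _COVARIATE_EDGES
    exo = ("amyloid", "age", "sex", "education", "hdac")
    covs = [Covariance(v, v) for v in COHORT_VARIABLES]
    for i, a in enumerate(exo):
        for b in exo[i + 1 :]:
            covs.append(Covariance(a, b))
    return PathModel(COHORT_VARIABLES, tuple(edges), tuple(covs))


def five_model_suite() -> dict:
    """The five constructs keyed in comparison-table order."""
    return {
        "hdac_mediation": hdac_mediation_model(),
        "hdac_after_atrophy": hdac_after_atrophy_model(),
        "hdac_first": hdac_first_model(),
        "hdac_between": hdac_between_model(),
        "classical_cascade": classical_cascade_model(),
    }


def mediation_true_params() -> dict:
    """Generating parameter values for the mediation construct.

    Standardized-scale paths; the tau -> {atrophy, cognition} direct effects
    are set so that the proportion of the tau effect mediated through HDAC is
    57% (atrophy) and 51% (cognition).  Exogenous variables are unit-variance
    and uncorrelated; residual variances keep endogenous variances near 1.
    """
    values = {
        "tau~amyloid": 0.65,
        "hdac~amyloid": -0.30,
        "hdac~tau": -0.50,
        "atrophy~amyloid": -0.05,
        "atrophy~tau": -0.18859649122807018,   # 0.25 / (0.25 + x) = 0.57
        "atrophy~hdac": 0.50,
        "cognition~amyloid": -0.05,
        "cognition~tau": -0.24019607843137258,  # 0.25 / (0.25 + x) = 0.51
        "cognition~hdac": 0.50,
        "cognition~atrophy": 0.0,
        "atrophy~age": -0.20,
        "atrophy~sex": -0.15,
        "atrophy~education": 0.0,
        "cognition~age": 0.0,
        "cognition~sex": 0.0,
        "cognition~education": 0.20,
    }
    model = hdac_mediation_model()
    for c in model.covariances:
        if not c.free:
            continue
        if c.a == c.b:
            if c.a in model.endogenous:
                sd = {"tau": 0.76, "hdac": 0.70, "atrophy": 0.70, "cognition": 0.70}[c.a]
                values[c.name] = sd**2
            else:
                values[c.name] = 1.0
        else:
            values[c.name] = 0.0
    return values
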