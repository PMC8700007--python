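"""Synthetic-data generators: lognormal expression groups, coverage
experiments for the ratio estimator, and random logic networks for
engine fuzzing.

Everything here is a pure function of (spec, seed): identical inputs
produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import ExpressionGroup, ratio_estimate
from .network import (HillParams, NetworkModel, Reaction, SpeciesNode, Term)

__all__ = [
    "ExpressionSimSpec",
    "RandomNetworkSpec",
    "gen_expression_groups",
    "coverage_experiment",
    "gen_random_network",
]

#: log-scale SD of the default fixture; nominal — chosen to give interval
#: widths on the order seen in small-n densitometry reanalyses
DEFAULT_SIGMA = 0.3


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Lognormal two-group expression simulation settings.

    ``ratio`` is the true ratio of group medians (KO over baseline);
    ``sigma`` the common log-scale SD; group sizes default to the n = 4
    typical of western-blot densitometry panels.
    """

    ratio: float = 2.0
    sigma: float = DEFAULT_SIGMA
    n_base: int = 4
    n_ko: int = 4
    base_median: float = 1.0
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self):
        if self.ratio <= 0 or self.sigma < 0 or self.base_median <= 0:
            raise ValueError("ratio and base_median must be > 0, sigma >= 0")
        if self.n_base < 2 or self.n_ko < 2:
            raise ValueError("group sizes must be at least 2")


def gen_expression_groups(spec: ExpressionSimSpec,
                          species: str = "speciesX") -> pd.DataFrame:
    """One replicate of a two-group lognormal expression table.

    Baseline values are lognormal with median ``base_median``; KO values
    with median ``base_median * ratio``; both share log-scale SD sigma.
    Returns the long-format table (sample_id, group, species, value)
    accepted verbatim by the ratio estimator.
    """
    rng = np.random.default_rng(spec.seed)
    mu_base = np.log(spec.base_median)
    mu_ko = mu_base + np.log(spec.ratio)
    base = np.exp(rng.normal(mu_base, spec.sigma, size=spec.n_base))
    ko = np.exp(rng.normal(mu_ko, spec.sigma, size=spec.n_ko))
    rows = [{"sample_id": f"B{i+1}", "group": "Baseline",
             "species": species, "value": v} for i, v in enumerate(base)]
    rows += [{"sample_id": f"K{i+1}", "group": "KO",
              "species": species, "value": v} for i, v in enumerate(ko)]
    return pd.DataFrame(rows)


def coverage_experiment(spec: ExpressionSimSpec) -> dict[str, float]:
    """Frequentist validation of the Bayesian 95% interval.

    Draws ``n_replicates`` independent two-group datasets from the spec,
    estimates the ratio of medians for each, and reports the fraction of
    credible intervals containing the true ratio plus the median point
    estimate and median interval width.
    """
    if spec.n_replicates < 100:
        raise ValueError("coverage_experiment needs n_replicates >= 100")
    rng = np.random.default_rng(spec.seed)
    mu_base = np.log(spec.base_median)
    mu_ko = mu_base + np.log(spec.ratio)
    hits = 0
    points, widths = [], []
    for _ in range(spec.n_replicates):
        base = np.exp(rng.normal(mu_base, spec.sigma, size=spec.n_base))
        ko = np.exp(rng.normal(mu_ko, spec.sigma, size=spec.n_ko))
        est = ratio_estimate(ExpressionGroup("KO", tuple(ko)),
                             ExpressionGroup("Base", tuple(base)),
                             n_points=4096)
        if est.contains(spec.ratio):
            hits += 1
        points.append(est.point)
        widths.append(est.ci_high - est.ci_low)
    return {
        "coverage": hits / spec.n_replicates,
        "median_point": float(np.median(points)),
        "median_width": float(np.median(widths)),
    }


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Random logic-network settings for engine fuzzing.

    Self-loops are excluded but cycles are allowed — real signaling
    networks contain feedback loops and the engine must stay bounded on
    them.
    """

    n_species: int = 8
    n_reactions: int = 10
    frac_inhibiting: float = 0.3
    frac_and: float = 0.3
    n_inputs: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2 or self.n_inputs < 1:
            raise ValueError("need at least 2 species and 1 input")
        if self.n_inputs >= self.n_species:
            raise ValueError("n_inputs must leave room for regulated species")
        if self.n_reactions < self.n_inputs:
            raise ValueError("need at least one reaction per input")


def gen_random_network(spec: RandomNetworkSpec) -> NetworkModel:
    """Generate a random valid logic network.

    The first ``n_inputs`` species are inputs with random weights; the
    remaining reactions pick random targets among non-input species,
    with 1–2 terms (AND with probability ``frac_and``) and each term
    inhibiting with probability ``frac_inhibiting``.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"S{i}" for i in range(spec.n_species)]
    species = tuple(
        SpeciesNode(name=n, role="input" if i < spec.n_inputs else "intracellular")
        for i, n in enumerate(names)
    )
    reactions = [
        Reaction(target=names[i], terms=(),
                 weight=float(np.round(rng.uniform(0.1, 1.0), 6)))
        for i in range(spec.n_inputs)
    ]
    non_input = names[spec.n_inputs:]
    for _ in range(spec.n_reactions - spec.n_inputs):
        target = non_input[rng.integers(len(non_input))]
        n_terms = 2 if rng.random() < spec.frac_and else 1
        pool = [n for n in names if n != target]
        srcs = rng.choice(len(pool), size=min(n_terms, len(pool)),
                          replace=False)
        terms = tuple(
            Term(source=pool[s],
                 inhibiting=bool(rng.random() < spec.frac_inhibiting))
            for s in srcs
        )
        reactions.append(Reaction(target=target, terms=terms,
                                  weight=float(np.round(rng.uniform(0.2, 1.0), 6))))
    return NetworkModel(species=species, reactions=tuple(reactions),
                        defaults=HillParams())
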