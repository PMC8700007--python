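"""The packaged smooth-muscle-cell signaling model and its condition
experiments.

The shipped network file is a reconstruction of a vascular SMC signaling
map (mechanical, growth-factor, inflammatory, Wnt and TGF-beta inputs
converging on the PI3K/AKT/mTOR axis) with 81 species and 138 reactions;
see the package methods note for its provenance and limitations.

Three experimental conditions are modeled by maximal-activation
overrides: Baseline (no override), conditional *Tsc1* knock-out
(TSC1/2 y_max = 0) and rapamycin-treated knock-out (additionally
mTORC1 y_max = 0, full inhibition of the rapamycin-sensitive complex).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkModel, parse_network, steady_state

__all__ = [
    "Condition",
    "CONDITIONS",
    "PhenotypePanel",
    "PhenotypeScore",
    "ActivityScore",
    "RatioReport",
    "ALIASES",
    "canonical_name",
    "load_smc_model",
    "apply_condition",
    "run_conditions",
    "activation_ratio",
    "phenotype_scores",
    "activity_scores",
]

#: Results-text synonyms -> canonical node names in the packaged file
ALIASES = {
    "p-S6K": "S6K",
    "p-S6": "S6",
    "p-4EBP1": "E4EBP1",
    "p-AKT": "AKT",
    "beta-catenin": "bCatenin",
    "β-catenin": "bCatenin",
    "collagen": "Collagen",
    "elastin": "Elastin",
    "degraded elastin": "ElastinDegraded",
    "TSC1/2": "TSC1_2",
    "Smad2/3": "Smad2_3",
    "LAMP1/2": "LAMP2",
}


def canonical_name(name: str) -> str:
    return ALIASES.get(name, name)


@dataclass(frozen=True)
class Condition:
    """Named y_max / input-weight overrides applied to the model."""

    name: str
    y_max: dict[str, float] = field(default_factory=dict)
    input_weights: dict[str, float] = field(default_factory=dict)


CONDITIONS = {
    "Baseline": Condition("Baseline"),
    "KO": Condition("KO", y_max={"TSC1_2": 0.0}),
    "Rapa": Condition("Rapa", y_max={"TSC1_2": 0.0, "mTORC1": 0.0}),
}


@dataclass(frozen=True)
class PhenotypePanel:
    """Species panels defining the three SMC phenotype axes.

    The degradative panel follows the Results-text membership (LAMP2);
    an alternative panel substituting LAMP1/2 jointly is available via
    :func:`PhenotypePanel.lamp12`.
    """

    contractile: tuple[str, ...] = ("SMMHC", "SMA", "SM22")
    synthetic: tuple[str, ...] = ("Col3a1", "Eln", "TIMP")
    degradative: tuple[str, ...] = ("LAMP2", "MMP2", "S6", "MITF", "bCatenin")
    clustering: tuple[str, ...] = ("SMA", "SM22", "SMMHC", "Collagen",
                                   "Elastin", "MMP2", "MITF", "bCatenin",
                                   "LAMP2")

    @classmethod
    def lamp12(cls) -> "PhenotypePanel":
        return cls(degradative=("LAMP1", "LAMP2", "MMP2", "S6", "MITF",
                                "bCatenin"))


DEFAULT_PANEL = PhenotypePanel()


@dataclass(frozen=True)
class PhenotypeScore:
    contractile: float
    synthetic: float
    degradative: float


@dataclass(frozen=True)
class ActivityScore:
    proliferation: float
    apoptosis: float
    degradative_activity: float


PROLIFERATION_SPECIES = ("S6", "bCatenin", "p38")
APOPTOSIS_SPECIES = ("FOXO",)
DEGRADATIVE_ACTIVITY_SPECIES = ("ElastinDegraded", "LAMP1", "LAMP2")

#: denominators below this are treated as zero when forming ratios
ZERO_TOL = 1e-9


def load_smc_model() -> NetworkModel:
    """Parse and return the packaged 81-species / 138-reaction SMC model."""
    text = (importlib.resources.files("smcnet.data") / "smc_network.txt"
            ).read_text(encoding="utf-8")
    return parse_network(text)


def apply_condition(model: NetworkModel, condition: Condition | str
                    ) -> NetworkModel:
    """Return a copy of the model with a condition's overrides applied."""
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    out = model.with_y_max({canonical_name(k): v
                            for k, v in condition.y_max.items()})
    if condition.input_weights:
        input_rx = {}
        for i, r in enumerate(model.reactions):
            if r.is_input:
                input_rx[r.target] = i
        weights = {}
        for name, w in condition.input_weights.items():
            name = canonical_name(name)
            if name not in input_rx:
                raise KeyError(f"no input reaction targets {name!r}")
            weights[input_rx[name]] = w
        out = out.with_weights(weights)
    return out


def run_conditions(model: NetworkModel,
                   conditions=("Baseline", "KO", "Rapa"),
                   tol: float = 1e-6, t_end: float = 40.0
                   ) -> dict[str, dict[str, float]]:
    """Steady states for each condition from the same initial state.

    All conditions share identical solver settings; non-convergence is
    reported with the offending condition named.
    """
    out = {}
    for cond in conditions:
        name = cond if isinstance(cond, str) else cond.name
        mod = apply_condition(model, cond)
        try:
            steady = steady_state(mod, tol=tol, t_end=t_end)
        except Exception as exc:
            raise RuntimeError(f"condition {name!r}: {exc}") from exc
        out[name] = dict(zip(mod.names, steady))
    return out


@dataclass(frozen=True)
class RatioReport:
    """Per-species ratio of steady activations between two conditions.

    Denominators below ``ZERO_TOL`` are not divided through: the entry
    is flagged ``"zero-denominator"`` (ratio = inf if the numerator is
    appreciable, indeterminate otherwise — never silently 0/0 = 1).
    """

    ratios: dict[str, float]
    flags: dict[str, str]

    def __getitem__(self, species: str) -> float:
        return self.ratios[canonical_name(species)]

    def flag(self, species: str) -> str:
        return self.flags.get(canonical_name(species), "ok")


def activation_ratio(numer: dict[str, float], denom: dict[str, float],
                     species: list[str] | None = None) -> RatioReport:
    """Elementwise ratio numer/denom of two steady states."""
    if species is None:
        species = list(numer)
    ratios: dict[str, float] = {}
    flags: dict[str, str] = {}
    for sp in species:
        name = canonical_name(sp)
        if name not in numer or name not in denom:
            raise KeyError(f"species {sp!r} absent from states")
        num = max(float(numer[name]), 0.0)
        den = float(denom[name])
        if den < ZERO_TOL:
            if num < ZERO_TOL:
                ratios[name] = float("nan")
                flags[name] = "indeterminate"
            else:
                ratios[name] = float("inf")
                flags[name] = "zero-denominator"
        else:
            ratios[name] = num / den
    return RatioReport(ratios=ratios, flags=flags)


def _panel_mean(state: dict[str, float], panel: tuple[str, ...]) -> float:
    if not panel:
        raise ValueError("empty phenotype panel")
    missing = [p for p in panel if canonical_name(p) not in state]
    if missing:
        raise KeyError(f"species missing from state: {missing}")
    return float(np.mean([max(state[canonical_name(p)], 0.0) for p in panel]))


def phenotype_scores(state: dict[str, float],
                     panel: PhenotypePanel = DEFAULT_PANEL) -> PhenotypeScore:
    """Contractile / synthetic / degradative scores: panel-mean activations."""
    return PhenotypeScore(
        contractile=_panel_mean(state, panel.contractile),
        synthetic=_panel_mean(state, panel.synthetic),
        degradative=_panel_mean(state, panel.degradative),
    )


def activity_scores(state: dict[str, float]) -> ActivityScore:
    """Cellular-activity scores: proliferation (mean of S6, β-catenin,
    p38), apoptosis (FOXO) and degradative activity (degraded elastin
    plus lysosomal LAMP proteins)."""
    return ActivityScore(
        proliferation=_panel_mean(state, PROLIFERATION_SPECIES),
        apoptosis=_panel_mean(state, APOPTOSIS_SPECIES),
        degradative_activity=_panel_mean(state, DEGRADATIVE_ACTIVITY_SPECIES),
    )
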