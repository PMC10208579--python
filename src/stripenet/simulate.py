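"""Steady-state simulator for the three-node stripe-forming circuit.

The network is an incoherent feedforward loop: an arabinose-responsive
sensor activates with inducer and represses both a regulator and the
fluorescent output; the regulator also represses the output. At low inducer
the regulator is free and silences the output; at high inducer the sensor
silences it directly; in between the output escapes both repressors and a
stripe (low-high-low) appears along the gradient.

The model is algebraic: each regulatory arm is a Hill function evaluated at
steady state. Mutations are cis-regulatory, so a mutant allele rescales only
its own node's promoter strength (beta) and the binding constants of the
repressors (or the inducer) acting on that node's cis-region.

Three generation modes make every downstream stage testable:

``mechanistic``
    expression of a combination is the circuit's steady state with all
    mutation effects applied together (epistasis arises from the Hill
    nonlinearities);
``multiplicative_null``
    expression of a combination is exactly the wild-type level times the
    product of its singles' fold changes -- the null hypothesis of the
    multiplicative epistasis model, realized without error;
``multiplicative_plus_interactions``
    the null, with chosen combinations additionally scaled by ``10**delta``
    at chosen inducer levels, so a known epistasis coefficient can be
    injected and its recovery checked.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_LEVELS,
    Genotype,
    InducerLevel,
    Node,
    NODE_ORDER,
    enumerate_genotypes,
)

MODES = ("mechanistic", "multiplicative_null", "multiplicative_plus_interactions")


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of the steady-state Hill model (a.u. and % arabinose).

    Defaults are tuned so the wild type forms a stripe: output expression at
    the medium level (0.0002%) strictly exceeds both 0% and 0.2%.
    """

    beta_sensor: float = 100.0
    basal_sensor: float = 0.01
    k_ara: float = 0.005  # % arabinose at half-maximal sensor activation
    n_ara: float = 1.0

    beta_regulator: float = 50.0
    basal_regulator: float = 0.02
    k_sr: float = 2.0  # sensor level half-repressing the regulator
    n_sr: float = 2.0

    beta_output: float = 1000.0
    basal_output: float = 0.01
    k_so: float = 30.0  # sensor level half-repressing the output
    n_so: float = 2.0
    k_ro: float = 5.0  # regulator level half-repressing the output
    n_ro: float = 2.0

    reporter_scale: float = 1.0

    def __post_init__(self) -> None:
        positive = (
            "beta_sensor beta_regulator beta_output "
            "k_ara k_sr k_so k_ro reporter_scale"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_ara", "n_sr", "n_so", "n_ro"):
            if getattr(self, name) < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1")
        for name in ("basal_sensor", "basal_regulator", "basal_output"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


# cis-regulatory knobs a mutation may rescale, per node
_OPERATOR_KEYS: dict[Node, tuple[str, ...]] = {
    Node.SENSOR: ("k_ara",),
    Node.REGULATOR: ("k_sr",),
    Node.OUTPUT: ("k_so", "k_ro"),
}


@dataclass(frozen=True)
class MutationEffect:
    """A cis-regulatory allele: multipliers on its node's own parameters.

    ``beta_mult`` rescales the node's promoter strength; ``operator_mults``
    rescales the binding constants of the repressions (or, for the sensor,
    the inducer response) acting at that node's cis-region. All multipliers
    of 1.0 is the wild-type allele.
    """

    node: Node
    beta_mult: float = 1.0
    operator_mults: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beta_mult <= 0:
            raise ValueError("beta_mult must be > 0")
        allowed = _OPERATOR_KEYS[self.node]
        for key, mult in self.operator_mults.items():
            if key not in allowed:
                raise ValueError(
                    f"operator {key!r} does not act at the {self.node.value} node "
                    f"(allowed: {allowed})"
                )
            if mult <= 0:
                raise ValueError("operator multipliers must be > 0")
        object.__setattr__(self, "operator_mults", dict(self.operator_mults))

    @property
    def is_wt(self) -> bool:
        return self.beta_mult == 1.0 and all(
            v == 1.0 for v in self.operator_mults.values()
        )


def _apply_effects(
    params: CircuitParams, effects: Sequence[MutationEffect]
) -> CircuitParams:
    seen: set[Node] = set()
    updates: dict[str, float] = {}
    beta_names = {
        Node.SENSOR: "beta_sensor",
        Node.REGULATOR: "beta_regulator",
        Node.OUTPUT: "beta_output",
    }
    for eff in effects:
        if eff.node in seen:
            raise ValueError(f"more than one mutation effect targets {eff.node.value}")
        seen.add(eff.node)
        bname = beta_names[eff.node]
        updates[bname] = updates.get(bname, getattr(params, bname)) * eff.beta_mult
        for key, mult in eff.operator_mults.items():
            updates[key] = updates.get(key, getattr(params, key)) * mult
    return dataclasses.replace(params, **updates) if updates else params


def _hill_act(x: float, k: float, n: float) -> float:
    return x**n / (k**n + x**n) if x > 0 else 0.0


def _hill_rep(x: float, k: float, n: float) -> float:
    return k**n / (k**n + x**n)


def steady_state(
    params: CircuitParams,
    effects: Sequence[MutationEffect] = (),
    inducer: float = 0.0,
) -> float:
    """Noiseless output-node fluorescence at one inducer concentration.

    Deterministic and strictly positive. At most one effect per node.
    """
    if inducer < 0:
        raise ValueError("inducer concentration must be non-negative")
    p = _apply_effects(params, effects)
    sensor = p.beta_sensor * (
        p.basal_sensor
        + (1 - p.basal_sensor) * _hill_act(inducer, p.k_ara, p.n_ara)
    )
    regulator = p.beta_regulator * (
        p.basal_regulator
        + (1 - p.basal_regulator) * _hill_rep(sensor, p.k_sr, p.n_sr)
    )
    output = p.beta_output * (
        p.basal_output
        + (1 - p.basal_output)
        * _hill_rep(sensor, p.k_so, p.n_so)
        * _hill_rep(regulator, p.k_ro, p.n_ro)
    )
    return p.reporter_scale * output


def sensor_response(
    params: CircuitParams, inducer: float, effect: MutationEffect | None = None
) -> float:
    """Sensor-node expression alone (monotone non-decreasing in inducer)."""
    if inducer < 0:
        raise ValueError("inducer concentration must be non-negative")
    p = _apply_effects(params, [effect] if effect else [])
    return p.beta_sensor * (
        p.basal_sensor + (1 - p.basal_sensor) * _hill_act(inducer, p.k_ara, p.n_ara)
    )


def is_stripe(
    values_by_level: Sequence[float],
) -> bool:
    """Stripe phenotype at (low, medium, high): medium strictly greatest."""
    low, medium, high = values_by_level
    return medium > low and medium > high


@dataclass(frozen=True)
class Interaction:
    """An injected epistatic deviation for one combination at one level.

    ``delta`` is in log10 fold-change units: the combination's noiseless
    expression is multiplied by ``10**delta``.
    """

    genotype: str
    level: str
    delta: float


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic assay.

    Defaults mirror the assay design: 10 mutant alleles per node, triplicate
    measurements at low (0%), medium (0.0002%) and high (0.2%) arabinose,
    with 10% multiplicative replicate noise.
    """

    mutants_per_node: int = 10
    n_replicates: int = 3
    replicate_cv: float = 0.10
    levels: tuple[InducerLevel, ...] = DEFAULT_LEVELS
    params: CircuitParams = field(default_factory=CircuitParams)
    interactions: tuple[Interaction, ...] = ()
    # bounded multiplier ranges mutant alleles are drawn from (log-uniform)
    beta_mult_range: tuple[float, float] = (0.4, 2.5)
    operator_mult_range: tuple[float, float] = (1 / 3, 3.0)

    def __post_init__(self) -> None:
        if self.mutants_per_node < 1:
            raise ValueError("mutants_per_node must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


@dataclass
class SimulatedDataset:
    """Tidy replicate-level fluorescence plus the noiseless ground truth."""

    data: pd.DataFrame  # genotype, node, inducer_label, inducer_pct, replicate, fluorescence
    truth: pd.DataFrame  # genotype, inducer_label, fluorescence (noiseless)
    mode: str
    config: SimulationConfig
    effects: dict[tuple[Node, int], MutationEffect]

    def wt_reference(self) -> pd.DataFrame:
        return self.truth[self.truth["genotype"] == "WT"]


def draw_mutation_effects(
    config: SimulationConfig, rng: np.random.Generator, max_tries: int = 2000
) -> dict[tuple[Node, int], MutationEffect]:
    """Draw one allele per (node, index), rejecting non-stripe singles.

    Mirrors the selection of the assayed mutants: alleles perturb expression
    quantitatively but every single mutant keeps the stripe phenotype at the
    three assay levels.
    """
    lo_b, hi_b = config.beta_mult_range
    lo_o, hi_o = config.operator_mult_range
    concs = [lvl.concentration for lvl in config.levels]
    effects: dict[tuple[Node, int], MutationEffect] = {}
    for node in NODE_ORDER:
        for idx in range(1, config.mutants_per_node + 1):
            for _ in range(max_tries):
                beta = math.exp(rng.uniform(math.log(lo_b), math.log(hi_b)))
                op = {
                    key: math.exp(rng.uniform(math.log(lo_o), math.log(hi_o)))
                    for key in _OPERATOR_KEYS[node]
                }
                cand = MutationEffect(node=node, beta_mult=beta, operator_mults=op)
                vals = [steady_state(config.params, [cand], c) for c in concs]
                if is_stripe(vals):
                    effects[(node, idx)] = cand
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"could not draw a stripe-retaining allele for {node.value}-{idx}"
                )
    return effects


def _effects_for(
    genotype: Genotype, effects: Mapping[tuple[Node, int], MutationEffect]
) -> list[MutationEffect]:
    return [
        effects[(node, genotype.allele(node))] for node in genotype.mutated_nodes()
    ]


def _noiseless_table(
    config: SimulationConfig,
    mode: str,
    effects: Mapping[tuple[Node, int], MutationEffect],
) -> pd.DataFrame:
    """Ground-truth fluorescence per genotype x level for the given mode."""
    genotypes = enumerate_genotypes(config.mutants_per_node)
    concs = {lvl.label: lvl.concentration for lvl in config.levels}

    # mechanistic values for WT and singles are needed in every mode
    mech: dict[tuple[str, str], float] = {}
    for g in genotypes:
        if mode == "mechanistic" or g.order <= 1:
            effs = _effects_for(g, effects)
            for label, c in concs.items():
                mech[(g.name(), label)] = steady_state(config.params, effs, c)

    inter = {}
    for ia in config.interactions:
        g = Genotype.from_name(ia.genotype)
        if g.order < 2:
            raise ValueError(
                f"interaction delta specified for order-{g.order} genotype "
                f"{ia.genotype!r}; deltas apply to combinations only"
            )
        if ia.level not in concs:
            raise ValueError(f"unknown inducer level {ia.level!r} in interaction")
        inter[(g.name(), ia.level)] = ia.delta

    rows = []
    for g in genotypes:
        name = g.name()
        for label in concs:
            if mode == "mechanistic" or g.order <= 1:
                val = mech[(name, label)]
            else:
                wt = mech[("WT", label)]
                val = wt
                for s in g.singles():
                    val *= mech[(s.name(), label)] / wt
                if mode == "multiplicative_plus_interactions":
                    val *= 10.0 ** inter.get((name, label), 0.0)
            rows.append((name, label, concs[label], val))
    return pd.DataFrame(
        rows, columns=["genotype", "inducer_label", "inducer_pct", "fluorescence"]
    )


def _node_label(name: str) -> str:
    if name == "WT":
        return "WT"
    return "+".join(term.split("-")[0] for term in name.split("+"))


def generate_dataset(
    config: SimulationConfig, mode: str = "mechanistic", seed: int = 0
) -> SimulatedDataset:
    """Simulate the full genotype panel with replicate noise.

    Returns one record per genotype x inducer level x replicate; replicate
    noise is multiplicative log-normal with mean 1 and the configured CV.
    Reproducible given ``seed``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    rng = np.random.default_rng(seed)
    effects = draw_mutation_effects(config, rng)
    truth = _noiseless_table(config, mode, effects)

    n_rep = config.n_replicates
    cv = config.replicate_cv
    n_rows = len(truth)
    if cv > 0:
        sigma = math.sqrt(math.log1p(cv**2))
        mult = np.exp(
            rng.normal(0.0, sigma, size=(n_rows, n_rep)) - sigma**2 / 2.0
        )
    else:
        mult = np.ones((n_rows, n_rep))

    data = truth.loc[truth.index.repeat(n_rep)].reset_index(drop=True)
    data["replicate"] = np.tile(np.arange(1, n_rep + 1), n_rows)
    data["fluorescence"] = data["fluorescence"].to_numpy() * mult.ravel()
    data.insert(1, "node", data["genotype"].map(_node_label))
    data = data[
        ["genotype", "node", "inducer_label", "inducer_pct", "replicate", "fluorescence"]
    ]
    return SimulatedDataset(
        data=data, truth=truth, mode=mode, config=config, effects=dict(effects)
    )


# ---------------------------------------------------------------------------
# Raw plate-reader emulation
# ---------------------------------------------------------------------------

#: assay conditions per plate; the metabolic-load control duplicates the high
#: level with IPTG and is carried as a pass-through QC column downstream.
PLATE_CONDITIONS: tuple[tuple[str, float], ...] = (
    ("low", 0.0),
    ("medium", 0.0002),
    ("high", 0.2),
    ("metabolic_load", 0.2),
)


@dataclass
class PlateLayoutConfig:
    """Plate-reader run layout and optics."""

    genotypes_per_plate: int = 50
    n_wt_wells: int = 3
    n_blank_wells: int = 1
    time_min: tuple[int, int, int] = (0, 300, 10)  # start, stop, step
    background_fluor: float = 50.0
    blank_od: float = 0.04
    od_capacity: float = 0.55
    growth_rate: float = 0.04  # logistic rate, 1/min
    t_mid: float = 150.0  # logistic midpoint, min
    t_peak: float = 180.0  # fluorescence time-profile peak, min
    od_noise_sd: float = 0.002
    fluor_noise_sd: float = 1.0
    # per-genotype additive OD offsets (e.g. +0.3 to trip the growth QC rule)
    growth_offsets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_wt_wells < 3:
            raise ValueError("each plate needs at least 3 WT wells")
        if self.n_blank_wells < 1:
            raise ValueError("each plate needs at least 1 media-blank well")


def _time_profile(t: np.ndarray, t_peak: float) -> np.ndarray:
    # rises, peaks at t_peak, then decays (maturation/dilution of GFP signal)
    return (t / t_peak) * np.exp(1.0 - t / t_peak)


def generate_raw_plates(
    config: SimulationConfig,
    seed: int = 0,
    layout: PlateLayoutConfig | None = None,
    mode: str = "mechanistic",
) -> pd.DataFrame:
    """Emulate raw plate-reader time series for the whole genotype panel.

    Genotypes are split into batches; each batch is measured on three
    replicate plates, each carrying one well per genotype and condition plus
    three WT wells and a media blank per condition. Output columns:
    ``plate, well, role, genotype, condition, inducer_pct, time_min, od, gfp``.
    Byte-identical on rerun with the same seed.
    """
    layout = layout or PlateLayoutConfig()
    rng = np.random.default_rng(seed)
    effects = draw_mutation_effects(config, rng)
    level_map = {lvl.label: lvl.concentration for lvl in config.levels}
    # raw plates always carry the four assay conditions
    truth_cfg = dataclasses.replace(
        config,
        levels=tuple(
            InducerLevel(lbl, pct)
            for lbl, pct in PLATE_CONDITIONS
            if lbl != "metabolic_load"
        ),
    )
    truth = _noiseless_table(truth_cfg, mode, effects)
    truth_map = {
        (r.genotype, r.inducer_label): r.fluorescence for r in truth.itertuples()
    }
    del level_map

    genotypes = [g.name() for g in enumerate_genotypes(config.mutants_per_node)]
    samples = [g for g in genotypes if g != "WT"]
    t0, t1, dt = layout.time_min
    t = np.arange(t0, t1 + dt, dt, dtype=float)
    prof = _time_profile(np.maximum(t, 1e-9), layout.t_peak)

    cv = config.replicate_cv
    sigma = math.sqrt(math.log1p(cv**2)) if cv > 0 else 0.0

    batches = [
        samples[i : i + layout.genotypes_per_plate]
        for i in range(0, len(samples), layout.genotypes_per_plate)
    ]
    frames = []
    for b, batch in enumerate(batches, start=1):
        for rep in range(1, config.n_replicates + 1):
            plate = f"B{b:02d}R{rep}"
            well_no = 0
            wells: list[tuple[str, str, str]] = []  # (role, genotype, condition)
            for cond, _pct in PLATE_CONDITIONS:
                for g in batch:
                    wells.append(("sample", g, cond))
                for _ in range(layout.n_wt_wells):
                    wells.append(("WT", "WT", cond))
                for _ in range(layout.n_blank_wells):
                    wells.append(("blank", "", cond))
            for role, g, cond in wells:
                well_no += 1
                well = f"W{well_no:03d}"
                pct = dict(PLATE_CONDITIONS)[cond]
                if role == "blank":
                    od = np.full_like(t, layout.blank_od)
                    gfp = np.full_like(t, layout.background_fluor)
                else:
                    truth_cond = "high" if cond == "metabolic_load" else cond
                    level = truth_map[(g, truth_cond)]
                    if sigma > 0:
                        level *= math.exp(rng.normal(0, sigma) - sigma**2 / 2)
                    cap = layout.od_capacity * math.exp(rng.normal(0, 0.02)) + (
                        layout.growth_offsets.get(g, 0.0) if role == "sample" else 0.0
                    )
                    od = layout.blank_od + cap / (
                        1 + np.exp(-layout.growth_rate * (t - layout.t_mid))
                    )
                    gfp = layout.background_fluor + level * (od - layout.blank_od) * prof
                if layout.od_noise_sd > 0:
                    od = od + rng.normal(0, layout.od_noise_sd, size=t.shape)
                if layout.fluor_noise_sd > 0:
                    gfp = gfp + rng.normal(0, layout.fluor_noise_sd, size=t.shape)
                frames.append(
                    pd.DataFrame(
                        {
                            "plate": plate,
                            "well": well,
                            "role": role,
                            "genotype": g,
                            "condition": cond,
                            "inducer_pct": pct,
                            "time_min": t,
                            "od": od,
                            "gfp": gfp,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
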