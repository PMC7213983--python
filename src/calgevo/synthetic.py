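"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one measured data class from the study system:
amino-acid alignments evolved on a known tree (for reconstruction tests),
proteinase-K gel time courses whose band areas decay as A0*exp(-k t),
two-state chemical-denaturation curves, logistic OD600 growth curves with
treatment-dependent lag and carrying capacity, and dual-luciferase reporter
plates with LPS / LPS+PB anchors.

Noise models are chosen for testability, not instrument fidelity:
multiplicative Gaussian for gel band areas and luciferase counts, additive
Gaussian for CD and OD600 signals. Every generator draws from a generator
seeded by the :class:`SimSpec`, so an identical spec reproduces identical
data bit-for-bit, and every generator returns its ground truth alongside
the data.

Named presets keep rate contrasts realistic for the system: an "hA9-like"
fast-degrading protein (k = 0.3 /min), a "complex-like" protease-resistant
heterocomplex (k = 3e-4 /min, three orders of magnitude slower), and a
stabilizing-mutation preset of ddG = 4 kcal/mol. The presets are
illustrative study-scale values, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, Alignment
from .assays import BLANK, LPS, LPS_PB, MOCK, UNTREATED, GrowthCurveSet, ReporterPlate
from .biophys import (
    DecayDataset,
    DenaturationCurve,
    KineticTrace,
    R_KCAL,
    T_STANDARD,
    two_state_signal,
)
from .densitometry import GelImage
from .phylo_asr import transition_matrix
from .trees import PhyloTree

__all__ = [
    "SimSpec",
    "HA9_LIKE_RATE",
    "COMPLEX_LIKE_RATE",
    "DDG_PRESET",
    "simulate_msa",
    "simulate_gel_timecourse",
    "simulate_decay_dataset",
    "simulate_denaturation",
    "simulate_kinetic_trace",
    "simulate_growth",
    "simulate_reporter_plate",
]

#: Fast-degrading homodimer-like decay rate (1/min).
HA9_LIKE_RATE = 0.3
#: Protease-resistant heterocomplex-like decay rate (1/min), 3 orders slower.
COMPLEX_LIKE_RATE = 3e-4
#: Stabilizing-substitution free-energy shift preset (kcal/mol).
DDG_PRESET = 4.0


@dataclass
class SimSpec:
    """Seed and noise/shape parameters shared by all generators."""

    seed: int
    gel_noise_sigma: float = 0.03  # fractional sd of band areas
    decay_noise_sigma: float = 0.05  # fractional sd of fraction-intact points
    cd_noise_sigma: float = 0.3  # mdeg, additive
    od_noise_sigma: float = 0.003  # OD600, additive
    reporter_noise_sigma: float = 0.05  # fractional sd of firefly counts
    renilla_scale: float = 1e5  # mean renilla counts per well
    gel_lane_width: int = 20  # pixels
    gel_lane_height: int = 120  # pixels
    gel_band_center: float = 60.0  # migration position of the band
    gel_band_sigma: float = 4.0  # band width (pixels)
    gel_background: tuple[float, float] = (2.0, 6.0)  # linear gradient ends
    gel_area_scale: float = 5000.0  # band area at fraction-intact 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimSpec requires an explicit seed")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng((self.seed, stream))

    def to_dict(self) -> dict:
        return asdict(self)


# ------------------------------------------------------------ sequence data


def simulate_msa(
    spec: SimSpec, tree: PhyloTree, n_sites: int
) -> tuple[Alignment, dict[str, str]]:
    """Evolve an alignment down the tree under the equal-rates model.

    The root sequence is drawn uniformly over the 20 states and each branch
    applies the Poisson-model transition probabilities for its length.
    Returns the tip alignment and the true sequence at every internal node
    (the generator's ground truth for reconstruction accuracy tests).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = spec.rng(stream=1)
    K = len(AMINO_ACIDS)
    states: dict[str, np.ndarray] = {}

    def evolve(node, parent_states):
        if parent_states is None:
            node_states = rng.integers(0, K, size=n_sites)
        else:
            P = transition_matrix(node.length)
            cum = np.cumsum(P, axis=1)
            u = rng.random(n_sites)
            node_states = (u[:, None] > cum[parent_states]).sum(axis=1)
        states[node.name] = node_states
        for child in node.children:
            evolve(child, node_states)

    evolve(tree.root, None)
    to_seq = lambda arr: "".join(AMINO_ACIDS[i] for i in arr)
    tips = {n: to_seq(states[n]) for n in tree.leaf_names}
    ancestors = {
        n.name: to_seq(states[n.name]) for n in tree.internal_nodes()
    }
    return Alignment(list(tips), [tips[n] for n in tips]), ancestors


# ----------------------------------------------------------------- gel data


def simulate_gel_timecourse(
    spec: SimSpec,
    k: float,
    times_min: list[float],
    amplitude: float = 1.0,
) -> tuple[GelImage, dict]:
    """Render a one-band-per-lane gel whose areas decay as A0*exp(-k t).

    Each time point occupies one lane; the band is a Gaussian along the
    migration axis whose integrated area is A0*exp(-k t)*(1 + eps) with
    multiplicative Gaussian noise eps, on top of a linear background
    gradient. Returns the image and the true areas/fractions.
    """
    if k <= 0:
        raise ValueError("decay rate must be positive")
    times = np.asarray(times_min, dtype=float)
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    rng = spec.rng(stream=2)
    H, W = spec.gel_lane_height, spec.gel_lane_width
    n_lanes = times.size
    pos = np.arange(H)
    shape = np.exp(-0.5 * ((pos - spec.gel_band_center) / spec.gel_band_sigma) ** 2)
    shape /= shape.sum()
    bg_lo, bg_hi = spec.gel_background
    background = bg_lo + (bg_hi - bg_lo) * pos / (H - 1)
    image = np.tile(background[:, None], (1, n_lanes * W))
    true_fracs = amplitude * np.exp(-k * times)
    eps = rng.normal(0.0, spec.gel_noise_sigma, size=n_lanes)
    areas = spec.gel_area_scale * true_fracs * (1.0 + eps)
    for lane, area in enumerate(areas):
        image[:, lane * W : (lane + 1) * W] += (area * shape / W)[:, None]
    truth = {
        "k_per_min": k,
        "amplitude": amplitude,
        "times_min": times.tolist(),
        "true_fractions": true_fracs.tolist(),
        "band_areas": areas.tolist(),
        "band_window": [
            int(spec.gel_band_center - 5 * spec.gel_band_sigma),
            int(spec.gel_band_center + 5 * spec.gel_band_sigma),
        ],
    }
    return GelImage(image, lane_times=tuple(times)), truth


def simulate_decay_dataset(
    spec: SimSpec,
    k: float,
    n_replicates: int = 3,
    n_times: int = 10,
    t_max_halflives: float = 3.0,
    amplitude: float = 1.0,
    protein: str = "",
) -> tuple[DecayDataset, dict]:
    """Replicate fraction-intact time courses with multiplicative noise.

    Time points span ~``t_max_halflives`` half-lives of the true rate so the
    decay is well determined at any k.
    """
    if k <= 0:
        raise ValueError("decay rate must be positive")
    rng = spec.rng(stream=3)
    t_max = t_max_halflives * np.log(2) / k
    times = np.linspace(0.0, t_max, n_times)
    rows = []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, spec.decay_noise_sigma, size=n_times)
        f = amplitude * np.exp(-k * times) * (1.0 + noise)
        for tt, ff in zip(times, f):
            rows.append(
                {"replicate": rep, "time_min": tt, "fraction_intact": ff}
            )
    data = DecayDataset(pd.DataFrame(rows), protein=protein)
    return data, {"k_per_min": k, "amplitude": amplitude}


# ------------------------------------------------------------- CD datasets


def simulate_denaturation(
    spec: SimSpec,
    b_f: float = -20.0,
    m_f: float = 0.1,
    b_u: float = -2.0,
    m_u: float = 0.05,
    dG: float = 8.0,
    m: float = 1.6,
    x_max: float = 9.0,
    n_points: int = 25,
    noise_sigma: float | None = None,
    protein: str = "",
) -> tuple[DenaturationCurve, dict]:
    """Two-state denaturation curve sampled on a uniform denaturant grid."""
    if m <= 0:
        raise ValueError("m-value must be positive")
    rng = spec.rng(stream=4)
    sigma = spec.cd_noise_sigma if noise_sigma is None else noise_sigma
    x = np.linspace(0.0, x_max, n_points)
    y = two_state_signal(x, b_f, m_f, b_u, m_u, dG, m, RT=R_KCAL * T_STANDARD)
    y = y + rng.normal(0.0, sigma, size=x.size)
    truth = {
        "b_f": b_f, "m_f": m_f, "b_u": b_u, "m_u": m_u,
        "dG_kcal_mol": dG, "m_kcal_mol_M": m, "Cm_M": dG / m,
    }
    return DenaturationCurve(x, y, protein=protein), truth


def simulate_kinetic_trace(
    spec: SimSpec,
    k_u: float,
    dead_time: float = 10.0,
    y_start: float = -15.0,
    y_end: float = -5.0,
    t_max: float | None = None,
    n_points: int = 60,
    noise_sigma: float | None = None,
    protein: str = "",
) -> tuple[KineticTrace, dict]:
    """Unfolding CD trace y(t) = y_inf + dy*exp(-k_u t) after a spike."""
    if k_u <= 0:
        raise ValueError("unfolding rate must be positive")
    rng = spec.rng(stream=5)
    sigma = spec.cd_noise_sigma if noise_sigma is None else noise_sigma
    t_max = 5.0 / k_u if t_max is None else t_max
    t = np.linspace(0.0, t_max, n_points)
    y = y_end + (y_start - y_end) * np.exp(-k_u * t)
    y = y + rng.normal(0.0, sigma, size=t.size)
    trace = KineticTrace(t, y, dead_time=dead_time, protein=protein)
    return trace, {"k_u_per_s": k_u, "dead_time_s": dead_time}


# ------------------------------------------------------------- assay data


@dataclass
class GrowthTreatment:
    """Logistic growth parameters for one treatment condition."""

    capacity: float = 0.5  # OD600 carrying capacity K
    rate: float = 0.02  # logistic growth rate r (1/min)
    lag_min: float = 180.0  # inflection time t_lag
    concentration_uM: float | None = None


def simulate_growth(
    spec: SimSpec,
    treatments: dict[str, GrowthTreatment],
    n_bio: int = 3,
    n_tech: int = 3,
    duration_hr: float = 13.0,
    interval_min: float = 15.0,
    blank_level: float = 0.04,
) -> tuple[GrowthCurveSet, dict]:
    """Logistic OD600 plate: blank + K/(1 + exp(-r (t - t_lag))) + noise.

    ``treatments`` must not redefine the reserved ``untreated``/``blank``
    labels unless an explicit untreated parameterization is wanted; an
    untreated control (default parameters) and flat blank wells are always
    present. Technical replicates share parameters and differ only by noise.
    """
    rng = spec.rng(stream=6)
    times = np.arange(0.0, duration_hr * 60.0 + 1e-9, interval_min)
    conditions = dict(treatments)
    conditions.setdefault(UNTREATED, GrowthTreatment())
    rows = []
    well = 0
    for bio in range(n_bio):
        for name, par in conditions.items():
            curve = blank_level + par.capacity / (
                1.0 + np.exp(-par.rate * (times - par.lag_min))
            )
            for _ in range(n_tech):
                od = curve + rng.normal(0.0, spec.od_noise_sigma, size=times.size)
                for tt, o in zip(times, od):
                    rows.append(
                        {
                            "well": f"W{well}",
                            "time_min": tt,
                            "od600": max(o, 0.0),
                            "treatment": name,
                            "concentration_uM": par.concentration_uM,
                            "bio_rep": bio,
                        }
                    )
                well += 1
        for _ in range(n_tech):  # flat blanks
            od = blank_level + rng.normal(0.0, spec.od_noise_sigma, size=times.size)
            for tt, o in zip(times, od):
                rows.append(
                    {
                        "well": f"W{well}",
                        "time_min": tt,
                        "od600": max(o, 0.0),
                        "treatment": BLANK,
                        "concentration_uM": None,
                        "bio_rep": bio,
                    }
                )
            well += 1
    truth = {
        name: asdict(par) for name, par in conditions.items()
    }
    truth["blank_level"] = blank_level
    return GrowthCurveSet(pd.DataFrame(rows)), truth


def simulate_reporter_plate(
    spec: SimSpec,
    true_inductions: dict[str, float],
    n_bio: int = 3,
    n_tech: int = 3,
    background_ratio: float = 0.05,
    span_ratio: float = 1.5,
    include_mock: bool = True,
) -> tuple[ReporterPlate, dict]:
    """Dual-luciferase plates realizing the requested induction values.

    Per well, renilla counts are drawn around a per-plate scale and firefly
    counts are renilla * (background + induction * span) with multiplicative
    noise, so the firefly/renilla ratio inverts exactly to the requested
    induction in the noiseless limit. LPS (induction 1) and LPS+PB
    (induction 0) anchors are added automatically.
    """
    inductions = dict(true_inductions)
    inductions.setdefault(LPS, 1.0)
    inductions.setdefault(LPS_PB, 0.0)
    if include_mock:
        inductions.setdefault(MOCK, 0.0)
    rng = spec.rng(stream=7)
    rows = []
    well = 0
    for bio in range(n_bio):
        plate_scale = spec.renilla_scale * rng.uniform(0.8, 1.2)
        for name, ind in inductions.items():
            target = background_ratio + ind * span_ratio
            for _ in range(n_tech):
                renilla = plate_scale * (
                    1.0 + rng.normal(0.0, spec.reporter_noise_sigma)
                )
                firefly = (
                    renilla
                    * target
                    * (1.0 + rng.normal(0.0, spec.reporter_noise_sigma))
                )
                rows.append(
                    {
                        "well": f"W{well}",
                        "treatment": name,
                        "concentration_uM": None,
                        "firefly": firefly,
                        "renilla": renilla,
                        "bio_rep": bio,
                    }
                )
                well += 1
    truth = {"true_inductions": inductions, "background_ratio": background_ratio,
             "span_ratio": span_ratio}
    return ReporterPlate(pd.DataFrame(rows)), truth
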