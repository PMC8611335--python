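"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators, each a pure function of its spec plus a seed:

``render_plate``
    Draws a bright circular "spotted population" on a darker plate
    background and places dark fruiting-body-like blobs inside it.  Each
    blob is a flat-core disk with a Gaussian edge rolloff, optional
    interior texture and optional bright dust specks; global pixel noise
    is added last.  The returned ground truth records each body's center,
    radius, true pixel footprint (pixels darker than half the body's
    depth in the noiseless render), and true interior mean/SD, so
    segmentation and trait measurement can be scored against truth.

``simulate_evolution``
    Trait trajectories for treatments x replicate populations x cycles x
    assay replicates: ancestral trait vector + cumulative deterministic
    treatment effect + population-level random walk (stochastic
    diversification) + per-assay measurement noise, with per-cycle
    extinction hazards.  Extinction strikes at the development step of a
    cycle, so an extinct population emits no record at that cycle or
    later.

``simulate_mix_assays``
    Spore-count tables for monoculture and 1:1-mix assays with log-normal
    count noise, back-computed from target one-way mixing effects so that
    recovery by ``social_stats`` is exact at zero noise and unbiased
    otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import PlateImage
from .social_stats import SurvivalLedger

__all__ = [
    "PlateSpec",
    "EvolutionSimSpec",
    "render_plate",
    "simulate_evolution",
    "simulate_mix_assays",
    "default_evolution_spec",
]

_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass
class PlateSpec:
    """Parameters of one rendered plate image (intensities in 8-bit grey)."""

    shape: tuple[int, int] = (512, 512)
    roi_center: tuple[float, float] | None = None  # default: image center
    roi_radius: float = 220.0
    n_bodies: int = 40
    body_radius_mean: float = 6.0
    body_radius_sd: float = 1.0
    interior_mean: float = 120.0
    interior_sd: float = 0.0
    background: float = 200.0
    plate_background: float = 165.0  # plate surface outside the spot
    noise_sd: float = 2.0
    #: Gaussian edge rolloff of the body boundary, in px.  This emulates the
    #: fixed optical blur of the imaging system, so it does not scale with
    #: body size; 0 gives hard-edged disks.
    edge_sigma: float = 0.5
    n_dust: int = 0
    dust_value: float = 255.0

    def __post_init__(self) -> None:
        for name in ("interior_mean", "background", "plate_background", "dust_value"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must lie in [0, 255], got {v}")
        if self.body_radius_mean <= 0:
            raise ValueError("body radius must be positive")
        if self.interior_mean >= self.background:
            raise ValueError("bodies must be darker than the spot background")


def _body_profile(r: float, sigma: float, window: int) -> np.ndarray:
    """Blob weight g in [0, 1] on a (2w+1)^2 grid centered on the body."""
    ax = np.arange(-window, window + 1, dtype=np.float64)
    d = np.hypot(ax[:, None], ax[None, :])
    if sigma <= 0:
        return (d <= r).astype(np.float64)
    g = np.where(d <= r, 1.0, np.exp(-((d - r) ** 2) / (2.0 * sigma**2)))
    return g


def render_plate(spec: PlateSpec, seed: int = 0, meta: dict | None = None) -> dict:
    """Render one plate; returns the image, masks, noiseless render and truth.

    Bodies are placed fully inside the ROI without overlap by rejection
    sampling (error after 10^4 failed attempts).  Deterministic given the
    seed.

    Returns a dict with keys ``plate`` (a :class:`PlateImage` whose pixels
    include all noise), ``noiseless`` (the quantized render before global
    noise and dust), and ``truth`` (a DataFrame with one row per body:
    center_row, center_col, radius_px, area_px2, interior_mean,
    interior_sd).
    """
    rng = np.random.default_rng(seed)
    rows, cols = spec.shape
    center = spec.roi_center if spec.roi_center is not None else ((rows - 1) / 2.0, (cols - 1) / 2.0)

    rr, cc = np.ogrid[:rows, :cols]
    roi = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= spec.roi_radius**2
    if not roi.any():
        raise ValueError("ROI lies outside the image")

    canvas = np.full(spec.shape, spec.plate_background, dtype=np.float64)
    canvas[roi] = spec.background
    depth = spec.background - spec.interior_mean

    # --- place bodies by rejection sampling ---------------------------------
    placed: list[tuple[float, float, float, float]] = []  # row, col, radius, sigma
    attempts = 0
    while len(placed) < spec.n_bodies:
        if attempts >= _MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not place {spec.n_bodies} non-overlapping bodies in the ROI "
                f"after {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        attempts += 1
        r = max(2.0, rng.normal(spec.body_radius_mean, spec.body_radius_sd))
        sigma = float(spec.edge_sigma)
        extent = r + 3.0 * sigma + 1.0
        margin = spec.roi_radius - extent
        if margin <= 0:
            raise ValueError("bodies are too large for the ROI")
        # uniform position over the allowed disk
        u, theta = rng.random(), rng.random() * 2 * math.pi
        rad = margin * math.sqrt(u)
        y = center[0] + rad * math.sin(theta)
        x = center[1] + rad * math.cos(theta)
        y_extent = r + 3.0 * sigma
        ok = all(
            math.hypot(y - py, x - px) > (y_extent + pr + 3.0 * ps + 2.0)
            for py, px, pr, ps in placed
        )
        if ok:
            placed.append((y, x, r, sigma))

    # --- draw bodies --------------------------------------------------------
    truth_rows = []
    for y, x, r, sigma in placed:
        window = int(math.ceil(r + 4.0 * sigma + 1.0))
        iy, ix = int(round(y)), int(round(x))
        g = _body_profile(r, sigma, window)
        ys = slice(iy - window, iy + window + 1)
        xs = slice(ix - window, ix + window + 1)
        patch = canvas[ys, xs]
        patch -= depth * g
        core = g >= 0.5
        if spec.interior_sd > 0:
            texture = rng.normal(0.0, spec.interior_sd, size=g.shape)
            patch[core] += texture[core]
        canvas[ys, xs] = patch
        truth_rows.append(
            {
                "center_row": iy,
                "center_col": ix,
                "radius_px": r,
                "window": (ys, xs),
                "core": core,
            }
        )

    noiseless = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)

    # ground truth from the quantized noiseless render: the true area is the
    # counted foreground (darker-than-background) footprint of each body;
    # interior statistics are taken over the flat core
    bg_level = int(round(spec.background))
    for row in truth_rows:
        ys, xs = row.pop("window")
        core = row.pop("core")
        w = core.shape[0] // 2
        ax = np.arange(-w, w + 1, dtype=np.float64)
        d = np.hypot(ax[:, None], ax[None, :])
        local = d <= row["radius_px"] + 4.0 * spec.edge_sigma + 0.5
        footprint = (noiseless[ys, xs] < bg_level) & local
        row["area_px2"] = int(footprint.sum())
        vals = noiseless[ys, xs][core].astype(np.float64)
        row["interior_mean"] = float(vals.mean())
        row["interior_sd"] = float(vals.std(ddof=0))

    # --- dust specks (recorded into the dust mask) --------------------------
    dust_mask = np.zeros(spec.shape, dtype=bool)
    noisy = canvas.copy()
    body_clearance = [(y, x, r + 3.0 * s + 3.0) for y, x, r, s in placed]
    attempts = 0
    n_placed_dust = 0
    while n_placed_dust < spec.n_dust and attempts < _MAX_PLACEMENT_ATTEMPTS:
        attempts += 1
        u, theta = rng.random(), rng.random() * 2 * math.pi
        rad = (spec.roi_radius - 6.0) * math.sqrt(u)
        y = center[0] + rad * math.sin(theta)
        x = center[1] + rad * math.cos(theta)
        if any(math.hypot(y - py, x - px) < d for py, px, d in body_clearance):
            continue
        speck_r = 1 + rng.integers(0, 2)
        speck = (rr - y) ** 2 + (cc - x) ** 2 <= speck_r**2
        dust_mask |= speck
        noisy[speck] = spec.dust_value
        n_placed_dust += 1

    if spec.noise_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    pixels = np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)

    plate = PlateImage(
        pixels=pixels, roi_mask=roi, dust_mask=dust_mask, meta=dict(meta or {})
    )
    truth = pd.DataFrame(truth_rows)
    return {"plate": plate, "noiseless": noiseless, "truth": truth}


# ---------------------------------------------------------------------------
# evolution simulation
# ---------------------------------------------------------------------------

#: Trait order used throughout the simulated tables.
SIM_TRAITS = ["fb_count", "fb_area_med_px2", "fb_density_med", "fb_hetero_med"]


@dataclass
class TreatmentSpec:
    """One treatment: partner category, trait effects and extinction hazard."""

    name: str
    category: str  # cooperator, cheater, antagonist or none
    #: total deterministic shift per trait accrued linearly over all cycles
    effect: np.ndarray = field(default_factory=lambda: np.zeros(4))
    #: per-cycle extinction probability; either a scalar or {cycle: hazard}
    hazard: float | dict = 0.0

    def hazard_at(self, cycle: int) -> float:
        if isinstance(self.hazard, dict):
            return float(self.hazard.get(cycle, 0.0))
        return float(self.hazard)


@dataclass
class EvolutionSimSpec:
    """Design of the simulated evolution experiment.

    Defaults mirror the real design: 8 treatments x 8 replicate
    populations evolved for 10 cycles, phenotyped in 3 independent assay
    replicates.  Trait units are those of the plate-level table
    (fruiting-body count; px^2; grey values).
    """

    treatments: list[TreatmentSpec]
    ancestor: np.ndarray = field(
        default_factory=lambda: np.array([400.0, 120.0, 110.0, 12.0])
    )
    #: per-trait SD of the population-level random walk, per cycle
    walk_sd: np.ndarray = field(
        default_factory=lambda: np.array([12.0, 3.0, 2.0, 0.5])
    )
    #: per-trait SD of assay (measurement) noise
    assay_sd: np.ndarray = field(
        default_factory=lambda: np.array([20.0, 5.0, 3.0, 0.8])
    )
    n_populations: int = 8
    n_cycles: int = 10
    n_assays: int = 3

    def __post_init__(self) -> None:
        for t in self.treatments:
            t.effect = np.asarray(t.effect, dtype=np.float64)
            if t.effect.shape != (4,):
                raise ValueError(f"treatment {t.name}: effect must be a 4-vector")
            for c in range(1, self.n_cycles + 1):
                h = t.hazard_at(c)
                if not (0.0 <= h <= 1.0):
                    raise ValueError(f"treatment {t.name}: hazard {h} outside [0, 1]")
        for name in ("ancestor", "walk_sd", "assay_sd"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (4,):
                raise ValueError(f"{name} must be a 4-vector")
            setattr(self, name, arr)
        if np.any(self.walk_sd < 0) or np.any(self.assay_sd < 0):
            raise ValueError("noise SDs must be non-negative")


def default_evolution_spec() -> EvolutionSimSpec:
    """The default simulated design, emulating the real experiment.

    Seven developmental-partner treatments plus a no-partner control.
    Cheater partners drive large decreases in fruiting-body count and
    size, the benign cooperator a moderate decrease, and antagonists
    little deterministic change but high extinction hazards; one
    antagonist is lethal enough that its populations are all lost in the
    early cycles.  Effects are expressed as total trait shifts accrued
    linearly over the 10 cycles.
    """
    return EvolutionSimSpec(
        treatments=[
            TreatmentSpec("no_dp", "none", np.array([-120.0, -15.0, -8.0, -1.5])),
            TreatmentSpec("coop_anc", "cooperator", np.array([-200.0, -20.0, -10.0, -2.0])),
            TreatmentSpec("cheat_a", "cheater", np.array([-260.0, -35.0, -15.0, -3.0])),
            TreatmentSpec("cheat_b", "cheater", np.array([-160.0, -30.0, -18.0, -2.5])),
            TreatmentSpec("cheat_c", "cheater", np.array([-380.0, -45.0, -20.0, -4.0])),
            TreatmentSpec(
                "antag_a", "antagonist", np.array([-40.0, -5.0, -2.0, -0.5]), hazard=0.05
            ),
            TreatmentSpec(
                "antag_b", "antagonist", np.array([-60.0, -8.0, -3.0, -0.8]), hazard=0.05
            ),
            TreatmentSpec(
                "antag_lethal", "antagonist", np.zeros(4), hazard=0.35
            ),
        ]
    )


def simulate_evolution(
    spec: EvolutionSimSpec, seed: int = 0
) -> tuple[pd.DataFrame, SurvivalLedger]:
    """Simulate trait trajectories and extinctions; deterministic given seed.

    Returns a ``traits.csv``-shaped table (one row per surviving
    population per cycle per assay replicate) and the survival ledger.
    """
    rng = np.random.default_rng(seed)
    records = []
    ledger_rows = []
    for trt in spec.treatments:
        step = trt.effect / spec.n_cycles
        for p in range(1, spec.n_populations + 1):
            pop_id = f"{trt.name}_P{p}"
            state = spec.ancestor.copy()
            extinction_cycle: int | None = None
            for cycle in range(1, spec.n_cycles + 1):
                if rng.random() < trt.hazard_at(cycle):
                    extinction_cycle = cycle
                    break
                state = state + step + rng.normal(0.0, spec.walk_sd)
                for a in range(1, spec.n_assays + 1):
                    obs = state + rng.normal(0.0, spec.assay_sd)
                    obs = np.maximum(obs, 0.0)
                    records.append(
                        {
                            "assay_id": f"A{a}",
                            "cycle": cycle,
                            "treatment": trt.name,
                            "population_id": pop_id,
                            "fb_count": int(round(obs[0])),
                            "fb_area_med_px2": obs[1],
                            "fb_density_med": obs[2],
                            "fb_hetero_med": obs[3],
                            "n_regions_used": int(round(obs[0])),
                        }
                    )
            ledger_rows.append(
                {
                    "treatment": trt.name,
                    "population_id": pop_id,
                    "extinction_cycle": extinction_cycle,
                }
            )
    traits = pd.DataFrame(records)
    ledger = SurvivalLedger(
        table=pd.DataFrame(ledger_rows).astype({"extinction_cycle": "float64"}),
        n_cycles=spec.n_cycles,
        populations_per_treatment=spec.n_populations,
    )
    return traits, ledger


# ---------------------------------------------------------------------------
# mix-assay simulation
# ---------------------------------------------------------------------------


def simulate_mix_assays(
    pairs: list[dict],
    n_replicates: int = 3,
    noise_sd_log10: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate monoculture and 1:1-mix spore counts for strain pairings.

    Each entry of ``pairs`` gives ``strain_i``, ``strain_j``, target
    one-way effects ``C_i`` and ``C_j`` (log10 units), monoculture mean
    counts ``pure_i`` / ``pure_j`` and optionally ``f_i`` (default 0.5).
    Counts are drawn log-normally: observed = mean * 10**N(0, noise_sd);
    mix counts are back-computed from the targets so that zero noise
    recovers C (and the implied B) exactly and noisy recovery is unbiased
    in log10 units.

    Returns the long ``spores.csv``-shaped table and a ground-truth table
    with the planted C values and the implied total-group effect B.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for pair in pairs:
        si, sj = pair["strain_i"], pair["strain_j"]
        f_i = float(pair.get("f_i", 0.5))
        f_j = 1.0 - f_i
        pure_i, pure_j = float(pair["pure_i"]), float(pair["pure_j"])
        C_i, C_j = float(pair["C_i"]), float(pair["C_j"])
        assay_id = f"{si}_vs_{sj}"
        mix_i_true = f_i * pure_i * 10.0**C_i
        mix_j_true = f_j * pure_j * 10.0**C_j
        B_true = math.log10(
            (mix_i_true + mix_j_true) / (f_i * pure_i + f_j * pure_j)
        )
        truth_rows.append(
            {"assay_id": assay_id, "strain_i": si, "strain_j": sj,
             "C_i": C_i, "C_j": C_j, "B": B_true, "f_i": f_i}
        )
        for rep in range(1, n_replicates + 1):
            noise = lambda: 10.0 ** rng.normal(0.0, noise_sd_log10)
            entries = [
                (si, None, "pure", pure_i * noise(), f_i),
                (sj, None, "pure", pure_j * noise(), f_j),
                (si, sj, "mix", mix_i_true * noise(), f_i),
                (sj, si, "mix", mix_j_true * noise(), f_j),
            ]
            for strain, partner, culture, count, freq in entries:
                rows.append(
                    {
                        "assay_id": assay_id,
                        "replicate": rep,
                        "strain": strain,
                        "partner_or_NA": partner if partner is not None else "NA",
                        "culture": culture,
                        "spore_count": count,
                        "initial_frequency": freq,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
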