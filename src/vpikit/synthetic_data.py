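"""Synthetic single-vesicle TIRF data with known ground truth.

Everything the analysis pipeline consumes can be generated here: random
protein point patterns on a surface, vesicle-docking outcomes under the
adsorption models, rendered camera image stacks, stepwise photobleaching
traces, binding-curve tables, and named on-disk fixture bundles.

The imaging defaults emulate a 60× TIRF setup with an sCMOS camera:
0.108 μm pixels, a 0.13 μm (sigma) diffraction-limited PSF, 100-ms frames,
and a ~100-μm field of view.  All randomness flows from a single integer
seed through ``numpy.random.SeedSequence`` substreams, so identical
(config, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import erf
from scipy.spatial import cKDTree

from .binding_models import (
    BindingCurve,
    CooperativeParams,
    HillParams,
    InhibitionParams,
    KineticParams,
    LangmuirParams,
    cooperative_Nb,
    hill_N,
    inhibition_N,
    kinetic_N,
    langmuir_Nb,
    particles_per_ml_to_pM,
)
from .imagestack import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "ProteinSurface",
    "VesicleField",
    "BleachTraceTruth",
    "simulate_protein_surface",
    "pair_sites",
    "simulate_vesicle_binding",
    "render_image_stack",
    "simulate_bleach_trace",
    "simulate_binding_timecourse",
    "generate_binding_table",
    "generate_fixture_dataset",
    "SCENARIO_NAMES",
]

#: log-normal sigma of per-vesicle label brightness; reproduces a peaked
#: spot-intensity histogram with a bright tail
BRIGHTNESS_SIGMA_LOG = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Imaging geometry, camera model and seed for all simulators.

    field_size : side length(s) of the field of view in μm
    pixel_size : μm per pixel (60× objective on an sCMOS)
    psf_sigma : Gaussian PSF sigma in μm
    photons_per_fluorophore : expected camera counts per fluorophore per frame
    read_noise_sd : additive Gaussian camera noise, counts
    camera_offset : constant camera baseline, counts
    crosstalk_matrix : optional (k, k) mixing matrix, entry [i, j] is the
        fraction of channel i signal bleeding into channel j; unit diagonal
    shot_noise : apply per-frame Poisson noise to the photon image
    """

    field_size: Union[float, Tuple[float, float]] = 102.4
    pixel_size: float = 0.108
    psf_sigma: float = 0.13
    frames: int = 10
    frame_interval: float = 0.1
    photons_per_fluorophore: float = 500.0
    read_noise_sd: float = 2.0
    camera_offset: float = 100.0
    crosstalk_matrix: Optional[np.ndarray] = None
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.field_dims
        if not (w > 0 and h > 0):
            raise ValueError("field_size must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.psf_sigma > 0:
            raise ValueError("psf_sigma must be > 0")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if self.read_noise_sd < 0 or self.camera_offset < 0:
            raise ValueError("read_noise_sd and camera_offset must be non-negative")
        if self.crosstalk_matrix is not None:
            m = np.asarray(self.crosstalk_matrix, dtype=float)
            _validate_crosstalk(m)
            object.__setattr__(self, "crosstalk_matrix", m)

    @property
    def field_dims(self) -> Tuple[float, float]:
        if np.isscalar(self.field_size):
            return float(self.field_size), float(self.field_size)
        w, h = self.field_size  # type: ignore[misc]
        return float(w), float(h)

    @property
    def n_pixels(self) -> Tuple[int, int]:
        """(rows, cols) of the rendered image."""
        w, h = self.field_dims
        return max(1, round(h / self.pixel_size)), max(1, round(w / self.pixel_size))

    @property
    def area_um2(self) -> float:
        w, h = self.field_dims
        return w * h

    def rng(self, stream: int = 0) -> np.random.Generator:
        """A deterministic substream of the top-level seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _validate_crosstalk(m: np.ndarray) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("crosstalk matrix must be square")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError("crosstalk matrix must have unit diagonal")
    off = m[~np.eye(m.shape[0], dtype=bool)]
    if np.any(off < 0) or np.any(off >= 1):
        raise ValueError("off-diagonal crosstalk must be in [0, 1)")


@dataclass
class ProteinSurface:
    """Random point pattern of surface proteins.

    points : (n, 2) array of (x, y) in μm
    multiplicity : fluorophores per point (>= 1; 2 for dimers)
    density : nominal molecules/μm² used for generation
    """

    points: np.ndarray
    multiplicity: np.ndarray
    density: float
    field_dims: Tuple[float, float]

    @property
    def n(self) -> int:
        return len(self.points)

    def emitter_photons(self, config: SimulationConfig) -> np.ndarray:
        return self.multiplicity * config.photons_per_fluorophore


@dataclass
class VesicleField:
    """Vesicles docked onto protein sites.

    site_class entries are ``"monomeric"`` or ``"paired"`` depending on
    which site class captured each vesicle.
    """

    bound_positions: np.ndarray  # (n, 2) μm
    brightness_factors: np.ndarray  # unitless, mean ~1
    site_class: np.ndarray  # str per vesicle

    @property
    def n(self) -> int:
        return len(self.bound_positions)

    def emitter_photons(self, config: SimulationConfig, photons: Optional[float] = None) -> np.ndarray:
        base = config.photons_per_fluorophore if photons is None else photons
        return self.brightness_factors * base


@dataclass
class BleachTraceTruth:
    """Ground truth for a stepwise photobleaching trace."""

    n_fluorophores: int
    step_size: float
    bleach_rate: float  # 1/s
    frames: int = 400
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        if self.n_fluorophores < 1:
            raise ValueError("n_fluorophores must be >= 1")
        if self.step_size <= 0 or self.bleach_rate <= 0:
            raise ValueError("step_size and bleach_rate must be > 0")


# ---------------------------------------------------------------------------
# point patterns and vesicle docking
# ---------------------------------------------------------------------------

def simulate_protein_surface(
    density: float,
    config: SimulationConfig,
    dimer_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> ProteinSurface:
    """Homogeneous spatial Poisson point process of surface proteins.

    The number of molecules is Poisson(density × area); positions are
    independent uniforms over the field.  A fraction ``dimer_fraction`` of
    points carries two fluorophores.
    """
    if density < 0:
        raise ValueError(f"density must be non-negative, got {density!r}")
    if not 0 <= dimer_fraction <= 1:
        raise ValueError(f"dimer_fraction must be in [0, 1], got {dimer_fraction!r}")
    rng = config.rng() if rng is None else rng
    w, h = config.field_dims
    n = rng.poisson(density * w * h)
    points = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    multiplicity = np.ones(n)
    if dimer_fraction > 0 and n > 0:
        multiplicity += (rng.random(n) < dimer_fraction).astype(float)
    return ProteinSurface(points=points, multiplicity=multiplicity, density=density, field_dims=(w, h))


def pair_sites(points: np.ndarray, reach: float):
    """Greedy distance-ascending mutual pairing of points within ``reach``.

    Returns ``(pairs, singles)`` where ``pairs`` is an (m, 2) integer array
    of point indices and ``singles`` the indices left unpaired.  Candidate
    pairs are processed in ascending distance (ties broken by index), so the
    closest mutual neighbours pair first; members of triplets and larger
    cliques that remain unpaired are treated as single sites.
    """
    n = len(points)
    if n == 0:
        return np.empty((0, 2), dtype=int), np.empty(0, dtype=int)
    tree = cKDTree(points)
    cand = tree.query_pairs(reach, output_type="ndarray")
    if len(cand) == 0:
        return np.empty((0, 2), dtype=int), np.arange(n)
    dist = np.linalg.norm(points[cand[:, 0]] - points[cand[:, 1]], axis=1)
    order = np.lexsort((cand[:, 1], cand[:, 0], dist))
    taken = np.zeros(n, dtype=bool)
    pairs = []
    for k in order:
        i, j = int(cand[k, 0]), int(cand[k, 1])
        if not taken[i] and not taken[j]:
            taken[i] = taken[j] = True
            pairs.append((i, j))
    pairs = np.asarray(pairs, dtype=int) if pairs else np.empty((0, 2), dtype=int)
    singles = np.flatnonzero(~taken)
    return pairs, singles


def simulate_vesicle_binding(
    surface: ProteinSurface,
    model: Union[LangmuirParams, CooperativeParams],
    vesicle_conc_pM: float,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> VesicleField:
    """Dock vesicles onto protein sites under an equilibrium adsorption model.

    For the cooperative model, proteins are partitioned into paired sites
    (greedy mutual pairing within the reach ``d``) and single sites; each
    site is independently occupied with probability α·V/(V + K_d,site) and
    an occupied site emits one vesicle at the site centroid.  The Langmuir
    model treats every protein as an independent site.
    """
    if vesicle_conc_pM < 0:
        raise ValueError("vesicle_conc must be non-negative")
    rng = config.rng(1) if rng is None else rng
    V = float(vesicle_conc_pM)

    if isinstance(model, LangmuirParams):
        centers = surface.points
        kd_pM = np.full(len(centers), model.K_d * 1e3)
        classes = np.array(["monomeric"] * len(centers))
        alpha = model.alpha
    elif isinstance(model, CooperativeParams):
        pairs, singles = pair_sites(surface.points, model.d)
        pair_centers = (
            (surface.points[pairs[:, 0]] + surface.points[pairs[:, 1]]) / 2.0
            if len(pairs)
            else np.empty((0, 2))
        )
        centers = np.vstack([surface.points[singles], pair_centers])
        kd_pM = np.concatenate(
            [np.full(len(singles), model.K_d1 * 1e3), np.full(len(pairs), model.K_d2 * 1e3)]
        )
        classes = np.array(["monomeric"] * len(singles) + ["paired"] * len(pairs))
        alpha = model.alpha
    else:
        raise TypeError(
            "unsupported model kind; supported kinds: LangmuirParams, CooperativeParams"
        )

    if len(centers) == 0 or V == 0:
        return VesicleField(
            bound_positions=np.empty((0, 2)),
            brightness_factors=np.empty(0),
            site_class=np.empty(0, dtype="<U9"),
        )
    p_occ = alpha * V / (V + kd_pM)
    occupied = rng.random(len(centers)) < p_occ
    n_bound = int(occupied.sum())
    z = rng.standard_normal(n_bound)
    brightness = np.exp(BRIGHTNESS_SIGMA_LOG * z - BRIGHTNESS_SIGMA_LOG**2 / 2.0)
    return VesicleField(
        bound_positions=centers[occupied],
        brightness_factors=brightness,
        site_class=classes[occupied],
    )


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _render_ideal(
    positions: np.ndarray, photons: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Expected photon image: pixel-integrated isotropic Gaussians."""
    rows, cols = config.n_pixels
    img = np.zeros((rows, cols))
    if len(positions) == 0:
        return img
    px = config.pixel_size
    sigma_px = config.psf_sigma / px
    halfw = int(math.ceil(6 * sigma_px)) + 1
    x_px = positions[:, 0] / px
    y_px = positions[:, 1] / px
    sq2 = math.sqrt(2.0) * sigma_px
    for x0, y0, p in zip(x_px, y_px, photons):
        c0 = max(0, int(math.floor(x0)) - halfw)
        c1 = min(cols, int(math.floor(x0)) + halfw + 1)
        r0 = max(0, int(math.floor(y0)) - halfw)
        r1 = min(rows, int(math.floor(y0)) + halfw + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        cc = np.arange(c0, c1)
        rr = np.arange(r0, r1)
        fx = 0.5 * (erf((cc + 0.5 - x0) / sq2) - erf((cc - 0.5 - x0) / sq2))
        fy = 0.5 * (erf((rr + 0.5 - y0) / sq2) - erf((rr - 0.5 - y0) / sq2))
        img[r0:r1, c0:c1] += p * np.outer(fy, fx)
    return img


def render_image_stack(
    emitters: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> ImageStack:
    """Render emitters into a noisy multi-channel camera image stack.

    Parameters
    ----------
    emitters : mapping of channel name -> (positions (n, 2) μm, photons (n,))
        Photon budgets are expected counts per frame (already including
        multiplicity and per-vesicle brightness factors).
    config : SimulationConfig
        Channel mixing via ``config.crosstalk_matrix`` (ordered like the
        mapping) is applied to the ideal photon images *before* noise.

    Each frame receives independent shot noise (Poisson in photons, if
    ``config.shot_noise``) and Gaussian read noise on top of the camera
    offset.
    """
    if config.psf_sigma < config.pixel_size / 4:
        logger.warning(
            "psf_sigma=%.3g μm is below pixel_size/4=%.3g μm: undersampled PSF",
            config.psf_sigma,
            config.pixel_size / 4,
        )
    names = list(emitters)
    w, h = config.field_dims
    for name in names:
        pos, phot = emitters[name]
        pos = np.asarray(pos, dtype=float)
        if len(pos) and (
            pos[:, 0].min() < 0 or pos[:, 1].min() < 0 or pos[:, 0].max() > w or pos[:, 1].max() > h
        ):
            raise ValueError(f"channel {name!r} has emitters outside the field bounds")
    rng = config.rng(2) if rng is None else rng

    ideal = {
        name: _render_ideal(np.asarray(emitters[name][0], dtype=float),
                            np.asarray(emitters[name][1], dtype=float), config)
        for name in names
    }
    if config.crosstalk_matrix is not None:
        m = config.crosstalk_matrix
        if m.shape[0] != len(names):
            raise ValueError("crosstalk matrix size does not match channel count")
        stack = np.stack([ideal[n] for n in names])  # (k, rows, cols)
        mixed = np.tensordot(m.T, stack, axes=1)  # observed_j = sum_i m[i,j] true_i
        ideal = {name: mixed[i] for i, name in enumerate(names)}

    rows, cols = config.n_pixels
    channels = {}
    for name in names:
        frames = np.empty((config.frames, rows, cols))
        for f in range(config.frames):
            photon_img = rng.poisson(ideal[name]).astype(float) if config.shot_noise else ideal[name]
            frame = photon_img + config.camera_offset
            if config.read_noise_sd > 0:
                frame = frame + rng.normal(0, config.read_noise_sd, size=(rows, cols))
            frames[f] = frame
        channels[name] = frames
    return ImageStack(
        channels=channels,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        meta={"camera_offset": config.camera_offset, "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# photobleaching traces and time courses
# ---------------------------------------------------------------------------

def simulate_bleach_trace(
    truth: BleachTraceTruth,
    noise_sd: float,
    rng: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Stepwise photobleaching trace with Gaussian noise.

    Each fluorophore bleaches at an exponentially distributed time with the
    given rate; the trace is step_size × (surviving count) sampled at frame
    times, plus N(0, noise_sd²) per frame.  The expected trace is
    non-increasing and terminates at zero background.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    bleach_times = rng.exponential(1.0 / truth.bleach_rate, size=truth.n_fluorophores)
    t = np.arange(truth.frames) * truth.frame_interval
    surviving = (bleach_times[None, :] > t[:, None]).sum(axis=1)
    trace = truth.step_size * surviving.astype(float)
    if noise_sd > 0:
        trace = trace + rng.normal(0, noise_sd, size=truth.frames)
    return trace


def simulate_binding_timecourse(
    kinetics: KineticParams,
    vesicle_conc_pM: float,
    times: Sequence[float],
    equilibrium: Union[LangmuirParams, CooperativeParams, None] = None,
    rho: Optional[float] = None,
    counting_area_um2: Optional[float] = None,
    rng: Union[int, np.random.Generator, None] = None,
) -> BindingCurve:
    """Single-exponential approach to binding equilibrium.

    N(t) = N_eq·(1 − exp(−k_obs·t)) with k_obs = k_on·V + k_off.  N_eq is
    taken from ``kinetics`` unless an equilibrium model and protein density
    are supplied.  If ``counting_area_um2`` is given, Poisson counting noise
    appropriate for that field area is added.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    if equilibrium is not None:
        if rho is None:
            raise ValueError("rho is required when an equilibrium model is given")
        if isinstance(equilibrium, LangmuirParams):
            n_eq = float(langmuir_Nb(rho, vesicle_conc_pM, equilibrium))
        else:
            n_eq = float(cooperative_Nb(rho, vesicle_conc_pM, equilibrium))
        kinetics = KineticParams(kinetics.k_on, kinetics.k_off, n_eq)
    y = kinetic_N(times, kinetics, vesicle_conc_pM)
    if counting_area_um2 is not None:
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        counts = rng.poisson(y * counting_area_um2)
        y = counts / counting_area_um2
    return BindingCurve(x=times, y_mean=y, x_kind="time", vesicle_conc_pM=vesicle_conc_pM)


# ---------------------------------------------------------------------------
# binding-curve tables
# ---------------------------------------------------------------------------

def generate_binding_table(
    model,
    x: Sequence[float],
    x_kind: str,
    n_rep: int = 5,
    cv: float = 0.10,
    vesicle_conc_pM: Optional[float] = None,
    rng: Union[int, np.random.Generator, None] = None,
) -> BindingCurve:
    """Replicated binding measurements with multiplicative measurement noise.

    The noiseless curve is evaluated from ``model`` (Langmuir / cooperative
    need ``vesicle_conc_pM``; Hill takes ``x`` as particle concentration;
    inhibition takes ``x`` as dose).  Each replicate is truth × (1 + cv·Z),
    floored at zero — a simple stand-in for counting noise at ~10% scale.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    if isinstance(model, LangmuirParams):
        truth = langmuir_Nb(x, vesicle_conc_pM, model)
    elif isinstance(model, CooperativeParams):
        truth = cooperative_Nb(x, vesicle_conc_pM, model)
    elif isinstance(model, HillParams):
        truth = hill_N(x, model)
    elif isinstance(model, InhibitionParams):
        truth = inhibition_N(x, model)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    reps = truth[:, None] * (1.0 + cv * rng.standard_normal((len(x), n_rep)))
    reps = np.clip(reps, 0.0, None)
    return BindingCurve.from_replicates(
        x, reps, x_kind=x_kind, vesicle_conc_pM=vesicle_conc_pM
    )


# ---------------------------------------------------------------------------
# named fixture scenarios
# ---------------------------------------------------------------------------

#: vesicle stock used throughout the binding scenarios: 2×10⁹ particles/ml
DEFAULT_VESICLE_CONC_PM = float(particles_per_ml_to_pM(2.0e9))

#: protein density grid (molecules/μm²) for density-dependence scenarios
DENSITY_GRID = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0)

#: capture-efficiency scale for vesicle-count scenarios; puts bound-vesicle
#: densities in the experimentally observed ~10⁻²–10⁻¹ vesicles/μm² range
SCENARIO_ALPHA = 0.1

U937_LANGMUIR = LangmuirParams(K_d=0.25, alpha=SCENARIO_ALPHA)
NK_COOPERATIVE = CooperativeParams(K_d1=130.0, K_d2=0.09, d=0.1, alpha=SCENARIO_ALPHA)
INHIBITION_TRUTH = InhibitionParams(N_0=0.06, N_bg=0.005, IC50=1.0, h=1.0)

#: densities for the intensity-vs-spot-density calibration ladder: six levels
#: well below the ~1 /μm² countability ceiling (diffraction-limited merging
#: already removes ~10% of maxima at 0.5 /μm²) plus three dense levels for
#: extrapolation
CALIBRATION_DENSITIES = (0.01, 0.03, 0.06, 0.1, 0.15, 0.25, 2.0, 10.0, 40.0)

SCENARIO_NAMES = (
    "calibration-ladder",
    "nk-like-cooperative",
    "u937-like-linear",
    "inhibition-dose-response",
    "colocalization-slb",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fixture_config(seed: int) -> SimulationConfig:
    # reduced 25.6-μm field keeps rendered fixtures light while preserving
    # the default optics
    return SimulationConfig(field_size=25.6, seed=seed)


def generate_fixture_dataset(scenario: str, seed: int, outdir) -> dict:
    """Write a named fixture bundle (images and/or tables + truth) to disk.

    Returns the manifest, which is also written as ``manifest.json`` and
    lists every file with its SHA-256 checksum.
    """
    if scenario not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIO_NAMES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: Dict[str, str] = {}
    truth: dict = {}
    ss = np.random.SeedSequence(seed)

    if scenario in ("u937-like-linear", "nk-like-cooperative"):
        model = U937_LANGMUIR if scenario == "u937-like-linear" else NK_COOPERATIVE
        curve = generate_binding_table(
            model,
            DENSITY_GRID,
            x_kind="density",
            n_rep=5,
            cv=0.10,
            vesicle_conc_pM=DEFAULT_VESICLE_CONC_PM,
            rng=np.random.default_rng(ss),
        )
        curve.to_csv(outdir / "binding_curve.csv")
        files["binding_curve.csv"] = _sha256(outdir / "binding_curve.csv")
        truth = {
            "model": type(model).__name__,
            "params": {k: getattr(model, k) for k in model.__dataclass_fields__},
            "vesicle_conc_pM": DEFAULT_VESICLE_CONC_PM,
        }

    elif scenario == "inhibition-dose-response":
        doses = np.logspace(-2, 2, 7)
        curve = generate_binding_table(
            INHIBITION_TRUTH, doses, x_kind="dose", n_rep=5, cv=0.10,
            rng=np.random.default_rng(ss),
        )
        curve.to_csv(outdir / "dose_response.csv")
        files["dose_response.csv"] = _sha256(outdir / "dose_response.csv")
        truth = {
            "model": "InhibitionParams",
            "params": {k: getattr(INHIBITION_TRUTH, k) for k in INHIBITION_TRUTH.__dataclass_fields__},
        }

    elif scenario == "calibration-ladder":
        config = _fixture_config(seed)
        rows = []
        for i, rho in enumerate(CALIBRATION_DENSITIES):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
            surface = simulate_protein_surface(rho, config, rng=rng)
            stack = render_image_stack(
                {"green": (surface.points, surface.emitter_photons(config))}, config, rng=rng
            )
            prefix = f"density_{i:02d}"
            manifest = stack.save(outdir, prefix=prefix)
            for fname in manifest["channels"].values():
                files[fname] = _sha256(outdir / fname)
            files[f"{prefix}_stack.json"] = _sha256(outdir / f"{prefix}_stack.json")
            tpath = outdir / f"{prefix}_truth.csv"
            _write_points_csv(tpath, surface.points, surface.multiplicity)
            files[tpath.name] = _sha256(tpath)
            rows.append({"index": i, "density_um2": rho, "n_molecules": surface.n})
        blank_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(99,)))
        blank = render_image_stack(
            {"green": (np.empty((0, 2)), np.empty(0))}, config, rng=blank_rng
        )
        manifest = blank.save(outdir, prefix="blank")
        for fname in manifest["channels"].values():
            files[fname] = _sha256(outdir / fname)
        files["blank_stack.json"] = _sha256(outdir / "blank_stack.json")
        truth = {"densities_um2": list(CALIBRATION_DENSITIES), "levels": rows,
                 "photons_per_fluorophore": config.photons_per_fluorophore}

    elif scenario == "colocalization-slb":
        config = _fixture_config(seed)
        rng = np.random.default_rng(ss)
        w, hgt = config.field_dims
        area = config.area_um2
        # membrane-embedded composition: most CD9 resides in ICAM-1/CD9
        # complexes, ICAM-1 is in excess (Fig-6-like composition)
        rho_complex, rho_icam_only, rho_cd9_only = 0.035, 0.085, 0.015
        n_cx = rng.poisson(rho_complex * area)
        n_io = rng.poisson(rho_icam_only * area)
        n_co = rng.poisson(rho_cd9_only * area)
        pts_cx = np.column_stack([rng.uniform(0, w, n_cx), rng.uniform(0, hgt, n_cx)])
        pts_io = np.column_stack([rng.uniform(0, w, n_io), rng.uniform(0, hgt, n_io)])
        pts_co = np.column_stack([rng.uniform(0, w, n_co), rng.uniform(0, hgt, n_co)])
        icam_pts = np.vstack([pts_cx, pts_io])
        cd9_pts = np.vstack([pts_cx, pts_co])
        # vesicles dock preferentially at complex sites (10x per-site odds)
        p_cx, p_io = 0.5, 0.05
        bound_cx = rng.random(n_cx) < p_cx
        bound_io = rng.random(n_io) < p_io
        ves_pts = np.vstack([pts_cx[bound_cx], pts_io[bound_io]])
        ves_bright = np.exp(
            BRIGHTNESS_SIGMA_LOG * rng.standard_normal(len(ves_pts))
            - BRIGHTNESS_SIGMA_LOG**2 / 2
        )
        stack = render_image_stack(
            {
                "green": (icam_pts, np.full(len(icam_pts), config.photons_per_fluorophore)),
                "red": (cd9_pts, np.full(len(cd9_pts), config.photons_per_fluorophore)),
                "farred": (ves_pts, ves_bright * config.photons_per_fluorophore),
            },
            config,
            rng=rng,
        )
        manifest = stack.save(outdir, prefix="slb")
        for fname in manifest["channels"].values():
            files[fname] = _sha256(outdir / fname)
        files["slb_stack.json"] = _sha256(outdir / "slb_stack.json")
        for name, pts in (("icam", icam_pts), ("cd9", cd9_pts), ("vesicles", ves_pts)):
            path = outdir / f"truth_{name}.csv"
            _write_points_csv(path, pts, np.ones(len(pts)))
            files[path.name] = _sha256(path)
        truth = {
            "rho_complex": rho_complex,
            "rho_icam_only": rho_icam_only,
            "rho_cd9_only": rho_cd9_only,
            "p_bound_complex": p_cx,
            "p_bound_icam_only": p_io,
            "n_complex": int(n_cx),
        }

    manifest = {"scenario": scenario, "seed": seed, "truth": truth, "files": files}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_points_csv(path: Path, points: np.ndarray, multiplicity: np.ndarray) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "x_um": points[:, 0] if len(points) else [],
            "y_um": points[:, 1] if len(points) else [],
            "multiplicity": multiplicity if len(points) else [],
        }
    ).to_csv(path, index=False)
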