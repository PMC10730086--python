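"""Synthetic confocal stacks, DE tables and landmark sets with ground truth.

Real shoot-apical-meristem (SAM) acquisitions are large and rarely
redistributable, so every downstream stage of this package can instead be
exercised on generated inputs whose true parameters are known exactly.  The
generators emulate:

* a dome-shaped meristem whose surface is a downward-opening paraboloid,
  imaged as a thin bright shell in a structural (cell-wall stain) channel;
* a reporter-protein domain centred ``d0`` micrometres below the apex,
  modelled as a separable Gaussian (axial spread ``sigma_ax``, lateral spread
  ``sigma_lat``) confined to the dome interior, over a constant background,
  with Poisson shot noise plus additive Gaussian detector noise, digitised
  to 16 bits;
* time-course differential-expression tables for a mutant/wild-type pair
  with three gene archetypes: unregulated background, a gradual moderate
  rise of mutant-vs-wild-type log2 fold change (trajectory (0, 0.5, 1) over
  days 7/10/13), and a strong early ectopic activation (trajectory
  (0, 4, 2));
* 2D sagittal landmark sets (meristem tip plus the two width-line
  endpoints) for width/height morphometrics.

Each generator is deterministic for a fixed seed and returns (or writes) a
truth sidecar sufficient to score any downstream estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stack import ImageStack, write_stack

#: half-width of a Gaussian at 10% of its maximum, in units of sigma
TEN_PERCENT_HALFWIDTH = math.sqrt(2.0 * math.log(10.0))  # ~2.1460


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

@dataclass
class StackParams:
    """Parameters of one synthetic two-channel meristem stack.

    Grid sizes are voxel counts; ``dx``/``dy``/``dz`` are voxel sizes in um
    (z-step default 0.4 um).  The apex is given in voxel coordinates
    ``(apex_ix, apex_iy, apex_iz)``; the dome surface is
    ``z(x, y) = z_apex + cx (x - x0)^2 + cy (y - y0)^2`` with curvatures in
    1/um.  The reporter domain peaks ``d0`` um below the apex with axial and
    lateral Gaussian spreads ``sigma_ax``/``sigma_lat`` and amplitude
    ``amplitude``; the structural channel is a shell of thickness
    ``shell_thickness`` and brightness ``shell_amplitude`` on the surface.
    Noise is Poisson on the clean signal (optional) plus additive Gaussian
    with sd ``gaussian_sd``.
    """

    nx: int = 161
    ny: int = 161
    nz: int = 300
    dx: float = 0.3
    dy: float = 0.3
    dz: float = 0.4
    apex_ix: int | None = None  # default: grid centre
    apex_iy: int | None = None
    apex_iz: int = 10
    cx: float = 0.02
    cy: float = 0.02
    d0: float = 50.0
    sigma_ax: float = 15.0
    sigma_lat: float = 12.0
    amplitude: float = 2000.0
    shell_thickness: float = 1.2
    shell_amplitude: float = 3000.0
    background: float = 5.0
    poisson_noise: bool = True
    gaussian_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apex_ix is None:
            self.apex_ix = self.nx // 2
        if self.apex_iy is None:
            self.apex_iy = self.ny // 2
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.sigma_ax <= 0 or self.sigma_lat <= 0:
            raise ValueError("spreads must be positive")
        if self.d0 < 0:
            raise ValueError("domain centre depth d0 must be >= 0")
        if self.cx <= 0 or self.cy <= 0:
            raise ValueError("dome curvatures must be positive")
        if not (0 <= self.apex_ix < self.nx and 0 <= self.apex_iy < self.ny
                and 0 <= self.apex_iz < self.nz):
            raise ValueError("apex must lie inside the grid")

    @property
    def apex_um(self) -> tuple[float, float, float]:
        return (self.apex_ix * self.dx, self.apex_iy * self.dy, self.apex_iz * self.dz)


@dataclass
class StackTruth:
    """Ground truth written alongside every generated stack."""

    apex_um: tuple[float, float, float]
    d0: float
    half_width_10pct: float          # sigma_ax * sqrt(2 ln 10)
    integrated_signal: float         # noise-free domain signal within the 10% band
    cx: float
    cy: float
    sigma_ax: float
    sigma_lat: float
    amplitude: float
    background: float

    def as_dict(self) -> dict:
        return {
            "apex_um": list(self.apex_um),
            "d0": self.d0,
            "half_width_10pct": self.half_width_10pct,
            "integrated_signal": self.integrated_signal,
            "cx": self.cx,
            "cy": self.cy,
            "sigma_ax": self.sigma_ax,
            "sigma_lat": self.sigma_lat,
            "amplitude": self.amplitude,
            "background": self.background,
        }


def _clean_channels(params: StackParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free structural and reporter channels plus the pure domain term."""
    p = params
    x0, y0, z_apex = p.apex_um
    x = np.arange(p.nx) * p.dx
    y = np.arange(p.ny) * p.dy
    z = np.arange(p.nz) * p.dz
    X, Y = np.meshgrid(x, y)                       # (ny, nx)
    r2 = (X - x0) ** 2 + (Y - y0) ** 2
    z_surf = z_apex + p.cx * (X - x0) ** 2 + p.cy * (Y - y0) ** 2
    Z = z[:, None, None]
    inside = Z >= z_surf[None, :, :]
    depth = Z - z_apex
    domain = (
        p.amplitude
        * np.exp(-((depth - p.d0) ** 2) / (2.0 * p.sigma_ax ** 2))
        * np.exp(-r2[None, :, :] / (2.0 * p.sigma_lat ** 2))
        * inside
    )
    reporter = domain + p.background
    shell = np.abs(Z - z_surf[None, :, :]) <= p.shell_thickness / 2.0
    structural = p.shell_amplitude * shell + p.background
    return structural, reporter, domain


def generate_stack(params: StackParams) -> tuple[ImageStack, StackTruth]:
    """Generate a two-channel synthetic meristem stack plus its truth sidecar.

    Channel 0 is the structural shell, channel 1 the reporter.  Output is
    16-bit unsigned with clipping; a clipping fraction above 0.1% raises a
    warning.  Raises ``ValueError`` if the domain centre lies deeper than
    the grid.
    """
    p = params
    if p.apex_um[2] + p.d0 > (p.nz - 1) * p.dz:
        raise ValueError(
            f"domain centre at depth {p.d0} um lies below the deepest slice"
        )
    structural, reporter, domain = _clean_channels(p)
    rng = np.random.default_rng(p.seed)
    channels = []
    for clean in (structural, reporter):
        img = rng.poisson(clean).astype(np.float64) if p.poisson_noise else clean.copy()
        if p.gaussian_sd > 0:
            img = img + rng.normal(0.0, p.gaussian_sd, size=img.shape)
        channels.append(img)
    data = np.stack(channels)
    saturated = np.count_nonzero(data > 65535)
    if saturated / data.size > 1e-3:
        warnings.warn(
            f"{saturated / data.size:.2%} of voxels saturate the 16-bit range",
            stacklevel=2,
        )
    data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)

    hw = p.sigma_ax * TEN_PERCENT_HALFWIDTH
    z = np.arange(p.nz) * p.dz
    depth = z - p.apex_um[2]
    in_band = (depth >= p.d0 - hw) & (depth <= p.d0 + hw)
    integrated = float(domain[in_band].sum())
    truth = StackTruth(
        apex_um=p.apex_um,
        d0=p.d0,
        half_width_10pct=hw,
        integrated_signal=integrated,
        cx=p.cx,
        cy=p.cy,
        sigma_ax=p.sigma_ax,
        sigma_lat=p.sigma_lat,
        amplitude=p.amplitude,
        background=p.background,
    )
    stack = ImageStack(
        data, p.dx, p.dy, p.dz, channel_names=("structural", "reporter")
    )
    return stack, truth


def save_stack(path: str | Path, params: StackParams) -> tuple[ImageStack, StackTruth]:
    """Generate a stack and write it (with its truth sidecar) to ``path``."""
    stack, truth = generate_stack(params)
    write_stack(path, stack, truth=truth.as_dict())
    return stack, truth


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimParams:
    """Parameters of the synthetic time-course DE tables.

    Three archetypes: ``background`` genes are unregulated everywhere;
    ``gradual`` genes rise moderately in the mutant (log2FC trajectory
    ``gradual_lfc`` over ``timepoints``, reaching ~1 by the last day);
    ``ectopic`` genes are strongly activated early (trajectory
    ``ectopic_lfc``, ~4 then ~2).  Adjusted p-values are drawn directly:
    Uniform(0, 1) for null contrasts and Beta(``p_alt_shape``, 1) for truly
    regulated ones — DE model fitting itself is out of scope, only the shape
    of its output matters here.  A fraction of each archetype is flagged as
    a "bound target" for enrichment testing.
    """

    n_background: int = 3000
    n_gradual: int = 535
    n_ectopic: int = 40
    timepoints: tuple[int, ...] = (7, 10, 13)
    gradual_lfc: tuple[float, ...] = (0.0, 0.5, 1.0)
    ectopic_lfc: tuple[float, ...] = (0.0, 4.0, 2.0)
    lfc_sd: float = 0.3
    bound_frac_regulated: float = 0.3
    bound_frac_background: float = 0.05
    p_alt_shape: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background + self.n_gradual + self.n_ectopic <= 0:
            raise ValueError("at least one gene must be requested")
        for traj in (self.gradual_lfc, self.ectopic_lfc):
            if len(traj) != len(self.timepoints):
                raise ValueError("trajectories need one value per timepoint")
        for frac in (self.bound_frac_regulated, self.bound_frac_background):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("bound fractions must lie in [0, 1]")
        if self.lfc_sd < 0:
            raise ValueError("lfc_sd must be >= 0")


def _gene_ids(params: ExpressionSimParams) -> tuple[list[str], np.ndarray]:
    labels = (
        ["background"] * params.n_background
        + ["gradual"] * params.n_gradual
        + ["ectopic"] * params.n_ectopic
    )
    n = len(labels)
    ids = [f"G{i:05d}" for i in range(n)]
    return ids, np.asarray(labels)


def generate_contrast_tables(
    params: ExpressionSimParams,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-contrast DE tables and the per-gene truth table.

    Returns a dict of contrast name -> DataFrame(gene_id, log2fc, padj,
    contrast) and a truth DataFrame(gene_id, archetype, bound_target).
    Within-genotype contrasts (later day vs day 7) are produced for the
    mutant ("tfl1") and wild type ("col0"); cross-genotype contrasts
    (mutant vs wild type) are produced for every timepoint.  Regulated
    archetypes deviate only in the mutant, so they are mutant-specific by
    construction.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    ids, archetype = _gene_ids(p)
    n = len(ids)

    traj = np.zeros((n, len(p.timepoints)))
    traj[archetype == "gradual"] = np.asarray(p.gradual_lfc)
    traj[archetype == "ectopic"] = np.asarray(p.ectopic_lfc)
    regulated = archetype != "background"

    bound = np.where(
        regulated,
        rng.random(n) < p.bound_frac_regulated,
        rng.random(n) < p.bound_frac_background,
    )

    def padj(active: np.ndarray) -> np.ndarray:
        out = rng.random(n)
        n_active = int(active.sum())
        if n_active:
            out[active] = rng.beta(p.p_alt_shape, 1.0, size=n_active)
        return out

    def noise() -> np.ndarray:
        return rng.normal(0.0, p.lfc_sd, size=n) if p.lfc_sd > 0 else np.zeros(n)

    tables: dict[str, pd.DataFrame] = {}

    def add(name: str, lfc: np.ndarray, active: np.ndarray) -> None:
        tables[name] = pd.DataFrame(
            {"gene_id": ids, "log2fc": lfc, "padj": padj(active), "contrast": name}
        )

    baseline = p.timepoints[0]
    for j, tp in enumerate(p.timepoints[1:], start=1):
        # mutant: regulated genes follow their trajectory relative to day 7
        add(f"tfl1_{tp}v{baseline}", traj[:, j] + noise(), regulated & (traj[:, j] != 0))
        # wild type: everything behaves like background
        add(f"col0_{tp}v{baseline}", noise(), np.zeros(n, dtype=bool))
    for j, tp in enumerate(p.timepoints):
        add(f"cross_{tp}", traj[:, j] + noise(), regulated & (traj[:, j] != 0))

    truth = pd.DataFrame(
        {"gene_id": ids, "archetype": archetype, "bound_target": bound}
    )
    return tables, truth


def generate_expression_matrix(
    params: ExpressionSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an FPKM matrix consistent with the configured trajectories.

    Columns are ``{genotype}_{timepoint}``; wild-type baselines are
    log-normal and the mutant equals baseline scaled by 2**trajectory.
    Returned together with the same truth table as the contrast tables.
    """
    p = params
    rng = np.random.default_rng(p.seed + 1)
    ids, archetype = _gene_ids(p)
    n = len(ids)
    traj = np.zeros((n, len(p.timepoints)))
    traj[archetype == "gradual"] = np.asarray(p.gradual_lfc)
    traj[archetype == "ectopic"] = np.asarray(p.ectopic_lfc)
    base = rng.lognormal(mean=2.0, sigma=1.0, size=n)
    cols = {}
    for j, tp in enumerate(p.timepoints):
        cols[f"col0_{tp}"] = base
        cols[f"tfl1_{tp}"] = base * 2.0 ** traj[:, j]
    fpkm = pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
    truth = pd.DataFrame({"gene_id": ids, "archetype": archetype})
    return fpkm, truth


def write_contrast_tables(
    out_dir: str | Path, params: ExpressionSimParams
) -> tuple[dict[str, Path], Path]:
    """Write each contrast as TSV plus a ``truth.tsv`` sidecar; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables, truth = generate_contrast_tables(params)
    paths = {}
    for name, tbl in tables.items():
        path = out_dir / f"{name}.tsv"
        tbl.to_csv(path, sep="\t", index=False)
        paths[name] = path
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return paths, truth_path


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def generate_landmarks(
    n: int = 20,
    width_range: tuple[float, float] = (30.0, 80.0),
    height_range: tuple[float, float] = (10.0, 40.0),
    rotate: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random sagittal landmark sets with analytic width/height truth.

    Each set has the two width-line endpoints (primordium axils) and the
    meristem tip at perpendicular distance ``height`` from the width line;
    sets are rigidly rotated/translated when ``rotate`` is true, which
    leaves the true measures unchanged.
    """
    rows = []
    truths = []
    for i in range(n):
        rng = np.random.default_rng((seed, i))  # pose draws cannot shift sizes
        w = rng.uniform(*width_range)
        h = rng.uniform(*height_range)
        ax1 = np.array([-w / 2.0, 0.0])
        ax2 = np.array([w / 2.0, 0.0])
        tip = np.array([rng.uniform(-w / 4.0, w / 4.0), h])
        if rotate:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s], [s, c]])
            shift = rng.uniform(-100.0, 100.0, size=2)
            ax1, ax2, tip = (R @ v + shift for v in (ax1, ax2, tip))
        rows.append(
            {
                "id": f"m{i:03d}",
                "timepoint": "7LD",
                "genotype": "col0",
                "tip_x": tip[0],
                "tip_y": tip[1],
                "ax1_x": ax1[0],
                "ax1_y": ax1[1],
                "ax2_x": ax2[0],
                "ax2_y": ax2[1],
            }
        )
        truths.append({"id": f"m{i:03d}", "width": w, "height": h})
    return pd.DataFrame(rows), pd.DataFrame(truths)
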