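"""Blood-pressure to photon-intensity lookup table: generation and inversion.

The table is built by sweeping arterial pressure over a grid (default
42-200 mmHg in 1 mmHg steps), rebuilding the voxel finger model at each
pressure — the artery diameter and absorption change with pressure — and
running the Monte Carlo simulation.  Detected intensity is normalized per
launched packet.

Monte Carlo noise can break strict monotonicity of intensity versus
pressure, and the blood-pressure inversion needs a single-valued map, so an
isotonic (pool-adjacent-violators) regression in the direction of the raw
table's overall trend is applied before piecewise-linear inverse
interpolation.

By default every pressure point reuses the same RNG seed (common random
numbers): the top-of-slab photon histories are then identical across
pressures and only the artery region decorrelates them, which strongly
suppresses point-to-point noise in the pressure differences.  Independent
per-pressure substreams are available via ``seed_strategy="split"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.isotonic import IsotonicRegression

from .mc import DetectorSpec, SourceSpec, run_simulation
from .tissue import FingerGeometrySpec, build_voxel_model

__all__ = ["IntensityTable", "generate_table", "monotonize", "invert_intensity"]


@dataclass
class IntensityTable:
    """Detected photon intensity versus arterial pressure.

    ``intensities`` are per-launched-packet detected weights; ``mc_se`` the
    Monte Carlo standard error per point.
    """

    pressures: np.ndarray
    intensities: np.ndarray
    mc_se: np.ndarray
    wavelength: float
    mode: str                      # "transmission" | "reflection"
    provenance: dict = field(default_factory=dict)
    monotone: bool = False

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mc_se = np.asarray(self.mc_se, dtype=float)
        if self.pressures.ndim != 1 or len(self.pressures) != len(self.intensities):
            raise ValueError("pressures and intensities must be 1D of equal length")
        if np.any(np.diff(self.pressures) <= 0):
            raise ValueError("pressures must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.pressures)

    def interp(self, pressure):
        """Intensity at arbitrary pressure by linear interpolation (clamped)."""
        return np.interp(pressure, self.pressures, self.intensities)

    def to_csv(self, path, sidecar: bool = True) -> None:
        df = pd.DataFrame({
            "pressure_mmHg": self.pressures,
            "intensity": self.intensities,
            "mc_se": self.mc_se,
        })
        df.to_csv(path, index=False)
        if sidecar:
            meta = dict(self.provenance, wavelength_nm=self.wavelength,
                        mode=self.mode, monotone=self.monotone)
            with open(str(path) + ".json", "w") as f:
                json.dump(meta, f, indent=2, default=str)

    @classmethod
    def from_csv(cls, path) -> "IntensityTable":
        df = pd.read_csv(path)
        meta = {}
        try:
            with open(str(path) + ".json") as f:
                meta = json.load(f)
        except FileNotFoundError:
            pass
        return cls(
            pressures=df["pressure_mmHg"].to_numpy(),
            intensities=df["intensity"].to_numpy(),
            mc_se=df["mc_se"].to_numpy() if "mc_se" in df else np.zeros(len(df)),
            wavelength=meta.get("wavelength_nm", float("nan")),
            mode=meta.get("mode", "transmission"),
            provenance=meta,
            monotone=bool(meta.get("monotone", False)),
        )


def generate_table(pressure_min: float = 42.0, pressure_max: float = 200.0,
                   step: float = 1.0, wavelength: float = 940,
                   mode: str = "transmission", n_photons: int = 1_000_000,
                   seed: int = 0, geometry: FingerGeometrySpec | None = None,
                   detector: DetectorSpec | None = None,
                   seed_strategy: str = "common",
                   progress: bool = False) -> IntensityTable:
    """Sweep the pressure grid and collect detected intensities.

    The grid has ``floor((max - min)/step) + 1`` points.  Each point rebuilds
    the voxel model (artery geometry and absorption updated) and runs the
    Monte Carlo engine.  ``seed_strategy`` is ``"common"`` (same stream every
    point, variance-cancelling for differences) or ``"split"`` (independent
    substreams derived from ``seed``).
    """
    if pressure_min > pressure_max:
        raise ValueError("pressure_min must not exceed pressure_max")
    if step <= 0:
        raise ValueError("step must be positive")
    if seed_strategy not in ("common", "split"):
        raise ValueError("seed_strategy must be 'common' or 'split'")
    geometry = geometry or FingerGeometrySpec()
    detector = detector or DetectorSpec(mode=mode)
    if detector.mode != mode:
        raise ValueError("detector mode does not match requested table mode")

    n_points = int(np.floor((pressure_max - pressure_min) / step)) + 1
    pressures = pressure_min + step * np.arange(n_points)
    if seed_strategy == "split":
        seeds = np.random.SeedSequence(seed).generate_state(n_points) % (2 ** 31)
    else:
        seeds = np.full(n_points, seed % (2 ** 31))

    intensities = np.empty(n_points)
    mc_se = np.empty(n_points)
    iterator = enumerate(pressures)
    if progress:
        from tqdm import tqdm

        iterator = enumerate(tqdm(pressures, desc="pressure sweep"))
    for i, p in iterator:
        try:
            grid = build_voxel_model(geometry, p, wavelength)
            res = run_simulation(
                grid, SourceSpec(), detector, n_photons=n_photons,
                seed=int(seeds[i]), record_fluence="none",
            )
        except Exception as exc:  # noqa: BLE001 - annotate failing pressure
            raise RuntimeError(f"simulation failed at {p} mmHg: {exc}") from exc
        intensities[i] = res.intensity
        mc_se[i] = res.detected_se

    return IntensityTable(
        pressures=pressures, intensities=intensities, mc_se=mc_se,
        wavelength=float(wavelength), mode=mode,
        provenance={
            "seed": seed, "seed_strategy": seed_strategy,
            "n_photons": n_photons,
            "lateral_extent_mm": geometry.lateral_extent,
            "voxel_pitch_mm": geometry.voxel_pitch,
            "detector_half_width_mm": detector.half_width,
        },
    )


def monotonize(table: IntensityTable) -> IntensityTable:
    """Isotonic regression of intensity on pressure, in the raw trend direction.

    The trend direction is the sign of the Spearman correlation between
    pressure and intensity; pool-adjacent-violators then produces the closest
    monotone sequence in least squares.  Idempotent.  A table with no overall
    trend cannot be oriented and raises (increase the photon budget).
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input yields nan rho
        rho = spearmanr(table.pressures, table.intensities).statistic
    if not np.isfinite(rho) or rho == 0:
        raise ValueError(
            "table has no monotone trend (Spearman rho = 0); "
            "increase the photon budget"
        )
    iso = IsotonicRegression(increasing=bool(rho > 0))
    fitted = iso.fit_transform(table.pressures, table.intensities)
    return replace(
        table, intensities=np.asarray(fitted, dtype=float), monotone=True,
        provenance=dict(table.provenance, monotonized=True,
                        trend="increasing" if rho > 0 else "decreasing"),
    )


def _check_monotone(values: np.ndarray) -> int:
    d = np.diff(values)
    if np.all(d >= 0):
        return 1
    if np.all(d <= 0):
        return -1
    raise ValueError("table is not monotone; call monotonize() first")


def invert_intensity(table: IntensityTable, intensity):
    """Pressure(s) whose table intensity matches ``intensity``.

    Piecewise-linear inverse interpolation on a monotone table.  Runs of
    equal intensity (flattened by isotonic regression) map to their mean
    pressure.  Out-of-range intensities clamp to the nearest endpoint
    pressure; the second return value flags them.

    Returns
    -------
    (pressure, out_of_range) with shapes matching the input.
    """
    direction = _check_monotone(table.intensities)
    I = table.intensities[::direction]
    P = table.pressures[::direction]
    # collapse flat runs to a single (intensity, mean pressure) knot
    uniq, start = np.unique(I, return_index=True)
    counts = np.diff(np.append(start, len(I)))
    p_knots = np.array([
        P[s:s + c].mean() for s, c in zip(start, counts)
    ])
    intensity = np.asarray(intensity, dtype=float)
    out_of_range = (intensity < uniq[0]) | (intensity > uniq[-1])
    pressure = np.interp(intensity, uniq, p_knots)
    if intensity.ndim == 0:
        return float(pressure), bool(out_of_range)
    return pressure, out_of_range
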