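"""Imaging-like synthetic chromatin-tracing datasets.

Turns simulated polymer trajectories into per-cell probe tables that mimic
multiplexed FISH chromatin tracing: coordinates in nm, Gaussian localization
noise, randomly missing probes, and two labeled populations.  "WT-like"
cells are drawn from the chromatin-like (two-domain) ensemble; "depleted-like"
cells are a mixture dominated by the unstructured reference ensemble, with a
minority of folded frames — emulating the observation that a substantial
fraction of cohesin-depleted cells still shows TAD-like structures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CellTrace", "SynthConfig", "generate_dataset", "write_traces", "read_traces"]


@dataclass
class CellTrace:
    """One cell's ordered probe positions.

    ``positions`` is (n_bins, 3) in nm with NaN rows for missing probes;
    ``missing_mask`` flags those rows; ``label`` is the cell population
    ("WT", "depleted", or "unknown").
    """

    cell_id: str
    positions: np.ndarray
    missing_mask: np.ndarray
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_bins, 3)")
        if self.missing_mask.shape != (self.positions.shape[0],):
            raise ValueError("missing_mask length must match positions")
        # missing probes must not carry finite coordinates
        self.positions = self.positions.copy()
        self.positions[self.missing_mask] = np.nan

    @property
    def n_bins(self) -> int:
        return self.positions.shape[0]


@dataclass
class SynthConfig:
    """Generator settings for the two-population synthetic dataset.

    ``nm_per_sigma = 150`` maps the simulation contact cutoff 3.0 sigma onto
    the 450 nm imaging cutoff.  ``mixture_weights`` is (reference fraction,
    chromatin-like fraction) for the depleted-like population; the default
    0.85/0.15 mirrors the >15% of cohesin-depleted cells with TAD-like
    structures.  ``noise_sd`` is the per-axis localization error in nm.
    """

    nm_per_sigma: float = 150.0
    noise_sd: float = 30.0
    missing_prob: float = 0.1
    n_cells_per_type: int = 2000
    mixture_weights: tuple[float, float] = (0.85, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_prob <= 1.0):
            raise ValueError("missing_prob must be in [0, 1]")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture_weights must sum to 1")
        if any(w < 0 for w in self.mixture_weights):
            raise ValueError("mixture_weights must be non-negative")


def _sample_frames(traj: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    if n > len(traj):
        warnings.warn(
            f"requested {n} cells from {len(traj)} unique frames; sampling with replacement",
            stacklevel=3,
        )
        idx = rng.integers(0, len(traj), size=n)
    else:
        idx = rng.choice(len(traj), size=n, replace=False)
    return traj[idx]


def generate_dataset(
    ref_traj: np.ndarray, chrom_traj: np.ndarray, cfg: SynthConfig
) -> list[CellTrace]:
    """Imaging-like two-population dataset from two simulated trajectories.

    WT-like cells are frames of ``chrom_traj``; depleted-like cells mix
    ``ref_traj`` and ``chrom_traj`` frames per ``cfg.mixture_weights``.
    Coordinates are scaled to nm, noised, and masked; fully reproducible
    from ``cfg.seed``.
    """
    ref_traj = np.asarray(ref_traj, dtype=float)
    chrom_traj = np.asarray(chrom_traj, dtype=float)
    if len(ref_traj) == 0 or len(chrom_traj) == 0:
        raise ValueError("trajectories must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells_per_type

    wt_frames = _sample_frames(chrom_traj, n, rng)

    n_from_chrom = int(rng.binomial(n, cfg.mixture_weights[1]))
    dep_frames = np.concatenate(
        [
            _sample_frames(ref_traj, n - n_from_chrom, rng),
            _sample_frames(chrom_traj, n_from_chrom, rng) if n_from_chrom else
            np.empty((0,) + chrom_traj.shape[1:]),
        ]
    )
    rng.shuffle(dep_frames, axis=0)

    cells: list[CellTrace] = []
    for label, frames in (("WT", wt_frames), ("depleted", dep_frames)):
        for k, conf in enumerate(frames):
            pos = conf * cfg.nm_per_sigma
            if cfg.noise_sd > 0:
                pos = pos + cfg.noise_sd * rng.standard_normal(pos.shape)
            missing = rng.random(pos.shape[0]) < cfg.missing_prob
            cells.append(
                CellTrace(
                    cell_id=f"{label}_{k:05d}",
                    positions=pos,
                    missing_mask=missing,
                    label=label,
                )
            )
    return cells


# --------------------------------------------------------------------------
# trace table I/O
# --------------------------------------------------------------------------

_COLUMNS = ["cell_id", "bin_index", "x_nm", "y_nm", "z_nm", "label"]


def write_traces(cells: list[CellTrace], path) -> None:
    """Write cells as a TSV with one row per probe; missing probes have empty coords."""
    records = []
    for c in cells:
        for b in range(c.n_bins):
            if c.missing_mask[b]:
                x = y = z = ""
            else:
                x, y, z = (f"{v:.4f}" for v in c.positions[b])
            records.append((c.cell_id, b, x, y, z, c.label))
    pd.DataFrame.from_records(records, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_traces(path) -> list[CellTrace]:
    """Read a trace TSV written by :func:`write_traces`; inverse of it."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "label": str})
    except pd.errors.EmptyDataError:
        logger.warning("empty trace file %s", path)
        return []
    if df.empty:
        logger.warning("trace file %s has no rows", path)
        return []
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file missing columns: {missing}")
    for col in ("x_nm", "y_nm", "z_nm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line and 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"non-numeric value in column {col} at line {line}")
        df[col] = coerced

    cells = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("bin_index")
        n = int(grp["bin_index"].max()) + 1
        pos = np.full((n, 3), np.nan)
        pos[grp["bin_index"].to_numpy()] = grp[["x_nm", "y_nm", "z_nm"]].to_numpy()
        mask = ~np.all(np.isfinite(pos), axis=1)
        label = grp["label"].iloc[0]
        cells.append(CellTrace(cell_id=str(cell_id), positions=pos,
                               missing_mask=mask, label=label))
    return cells
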