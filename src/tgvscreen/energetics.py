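"""Post-docking and post-MD bookkeeping.

Three independent pieces:

* best-combination screening over a docking score table (lowest energy wins,
  optionally restricted to one receptor);
* MM/PBSA component aggregation over trajectory snapshots, with the identity
  ΔG_gas = ΔE_vdw + ΔE_ele and ΔG_total = ΔG_gas + ΔG_solv enforced;
* hydrogen-bond occupancy statistics over per-frame donor/acceptor records.

All energies are in kcal/mol.  Standard deviations use the sample (n−1)
form, the convention of MM/PBSA reporting tools.  CSV inputs are
comma-separated with a header row; the Unicode minus sign that often
survives table transcription is normalized to the ASCII hyphen-minus.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EnergyTableError

#: Characters normalized to ASCII '-' when reading transcribed tables.
_MINUS_VARIANTS = {"−": "-", "–": "-", "—": "-"}

MMPBSA_COLUMNS = ("evdw", "eele", "gsolv", "ggas", "gtotal")


def _normalize_minus(value):
    if isinstance(value, str):
        for bad, good in _MINUS_VARIANTS.items():
            value = value.replace(bad, good)
    return value


@dataclass(frozen=True)
class DockingScoreTable:
    """Rows of (molecule id, target id, docking energy in kcal/mol)."""

    rows: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        seen = set()
        for mol, target, energy in self.rows:
            if not np.isfinite(energy):
                raise EnergyTableError(f"non-finite energy for ({mol}, {target})")
            if (mol, target) in seen:
                raise EnergyTableError(f"duplicate (molecule, target) pair ({mol}, {target})")
            seen.add((mol, target))

    @property
    def targets(self) -> set[str]:
        return {t for _m, t, _e in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["molecule", "target", "energy"])


@dataclass(frozen=True)
class EnergyComponents:
    """Mean ± sample std of each MM/PBSA component over n snapshots."""

    means: dict[str, float]
    stds: dict[str, float]
    n_snapshots: int

    def __post_init__(self):
        for key in MMPBSA_COLUMNS:
            if key not in self.means or key not in self.stds:
                raise EnergyTableError(f"missing component {key!r}")
        if abs(self.means["ggas"] - (self.means["evdw"] + self.means["eele"])) > 1e-9:
            raise EnergyTableError("ΔG_gas must equal ΔE_vdw + ΔE_ele")
        if abs(self.means["gtotal"] - (self.means["ggas"] + self.means["gsolv"])) > 1e-9:
            raise EnergyTableError("ΔG_total must equal ΔG_gas + ΔG_solv")
        if any(s < 0 for s in self.stds.values()):
            raise EnergyTableError("negative standard deviation")


@dataclass(frozen=True)
class HBondFrame:
    """One trajectory frame: its index and the (donor, acceptor) bonds seen."""

    frame: int
    bonds: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class OccupancySummary:
    """Per-pair occupancy (% of frames) and mean hydrogen bonds per frame."""

    occupancy: dict[tuple[str, str], float]
    mean_bonds_per_frame: float
    n_frames: int


def best_combination(
    table: DockingScoreTable, target: str | None = None
) -> tuple[str, str, float]:
    """The (molecule, target, energy) row with the lowest docking energy.

    Restricted to one receptor if ``target`` is given.  Ties break by
    molecule id then target id ascending.
    """
    rows = table.rows
    if target is not None:
        if target not in table.targets:
            raise EnergyTableError(f"unknown target {target!r}")
        rows = tuple(r for r in rows if r[1] == target)
    if not rows:
        raise EnergyTableError("empty docking score table")
    return min(rows, key=lambda r: (r[2], r[0], r[1]))


def aggregate_snapshots(samples: pd.DataFrame) -> EnergyComponents:
    """Aggregate per-snapshot MM/PBSA components into means ± sample stds.

    ``samples`` needs columns ``evdw``, ``eele``, ``gsolv`` (kcal/mol, one
    row per snapshot); ΔG_gas and ΔG_total are derived per snapshot by
    summation before averaging, so the component identities hold exactly.
    """
    required = ("evdw", "eele", "gsolv")
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise EnergyTableError(f"missing snapshot columns: {', '.join(missing)}")
    if len(samples) == 0:
        raise EnergyTableError("at least one snapshot is required")
    work = samples.loc[:, list(required)].astype(float).copy()
    for col in required:
        bad = work.index[~np.isfinite(work[col])]
        if len(bad) > 0:
            raise EnergyTableError(f"non-finite {col} at snapshot {bad[0]}")
    work["ggas"] = work["evdw"] + work["eele"]
    work["gtotal"] = work["ggas"] + work["gsolv"]
    n = len(work)
    means = {c: float(work[c].mean()) for c in MMPBSA_COLUMNS}
    stds = {c: (float(work[c].std(ddof=1)) if n > 1 else 0.0) for c in MMPBSA_COLUMNS}
    return EnergyComponents(means=means, stds=stds, n_snapshots=n)


def totals_from_means(
    evdw: float | None = None,
    eele: float | None = None,
    gsolv: float | None = None,
    ggas: float | None = None,
) -> tuple[float, float]:
    """Derive (ΔG_gas, ΔG_total) from component means, rounded to 2 dp.

    Either pass the three components (``evdw``, ``eele``, ``gsolv``) or a
    pre-summed gas term (``ggas``) plus ``gsolv``.  Rounding is
    round-half-even at two decimals, the precision MM/PBSA tables print.
    """
    if gsolv is None:
        raise EnergyTableError("gsolv is required")
    if ggas is None:
        if evdw is None or eele is None:
            raise EnergyTableError("need either (evdw, eele) or ggas")
        ggas = evdw + eele
    for value in (ggas, gsolv):
        if not np.isfinite(value):
            raise EnergyTableError("non-finite energy input")
    gtotal = ggas + gsolv
    return round(ggas, 2), round(gtotal, 2)


def hbond_stats(frames: list[HBondFrame]) -> OccupancySummary:
    """Occupancy per donor/acceptor pair and mean bonds per frame.

    A pair occurring several times within one frame counts once toward its
    occupancy but each occurrence counts toward bonds-per-frame.
    """
    if not frames:
        raise EnergyTableError("at least one frame is required")
    indices = [f.frame for f in frames]
    if len(set(indices)) != len(indices):
        raise EnergyTableError("duplicate frame indices")
    n = len(frames)
    present: dict[tuple[str, str], int] = {}
    total_bonds = 0
    for fr in frames:
        total_bonds += len(fr.bonds)
        for pair in set(fr.bonds):
            present[pair] = present.get(pair, 0) + 1
    occupancy = {pair: 100.0 * count / n for pair, count in present.items()}
    return OccupancySummary(
        occupancy=occupancy, mean_bonds_per_frame=total_bonds / n, n_frames=n
    )


# --- file formats -----------------------------------------------------------

def read_docking_table(path: str | Path) -> DockingScoreTable:
    """Read a docking score CSV with columns molecule,target,energy."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("molecule", "target", "energy") if c not in df.columns]
    if missing:
        raise EnergyTableError(f"missing docking columns: {', '.join(missing)}")
    energies = df["energy"].map(_normalize_minus).astype(float)
    rows = tuple(
        (str(m), str(t), float(e))
        for m, t, e in zip(df["molecule"], df["target"], energies)
    )
    return DockingScoreTable(rows=rows)


def read_snapshots(path: str | Path) -> pd.DataFrame:
    """Read a per-snapshot MM/PBSA CSV (snapshot,evdw,eele,gsolv)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("evdw", "eele", "gsolv"):
        if col in df.columns:
            df[col] = df[col].map(_normalize_minus).astype(float)
    return df


def read_hbond_frames(path: str | Path) -> list[HBondFrame]:
    """Read frame-wise hydrogen-bond records (frame,donor,acceptor).

    A frame listed with empty donor/acceptor fields contributes zero bonds
    but still counts toward the frame total.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("frame", "donor", "acceptor") if c not in df.columns]
    if missing:
        raise EnergyTableError(f"missing hbond columns: {', '.join(missing)}")
    frames: dict[int, list[tuple[str, str]]] = {}
    for idx, donor, acceptor in zip(df["frame"], df["donor"], df["acceptor"]):
        frames.setdefault(int(idx), [])
        if isinstance(donor, str) and donor.strip() and isinstance(acceptor, str) and acceptor.strip():
            frames[int(idx)].append((donor.strip(), acceptor.strip()))
    return [HBondFrame(frame=i, bonds=tuple(b)) for i, b in sorted(frames.items())]


def load_reference_docking() -> DockingScoreTable:
    """Published docking energies of the six thunder-god-vine triterpene
    representatives against PPARG and PTGS2 (kcal/mol)."""
    with resources.files("tgvscreen.data").joinpath("docking_pparg_ptgs2.csv").open() as fh:
        return read_docking_table(fh)


def load_reference_mmpbsa(target: str) -> pd.DataFrame:
    """Published MM/PBSA component means ± stds for the six representatives
    bound to PPARG or PTGS2, one row per complex (kcal/mol)."""
    target = target.upper()
    if target not in ("PPARG", "PTGS2"):
        raise EnergyTableError(f"unknown target {target!r}")
    name = f"mmpbsa_{target.lower()}.csv"
    with resources.files("tgvscreen.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh)
    for col in df.columns[1:]:
        df[col] = df[col].map(_normalize_minus).astype(float)
    return df
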