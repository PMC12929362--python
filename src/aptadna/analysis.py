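"""Trajectory descriptors for conformational preservation.

Two descriptors judge whether a converted aptamer keeps its parent fold over
a molecular-dynamics trajectory:

* **superposition RMSD** — per-frame root-mean-square deviation against a
  fixed reference after optimal rigid-body superposition (Kabsch algorithm,
  mass-weighted by default, reported in nm);
* **intramolecular hydrogen-bond count** — per-frame geometric detection
  with the conventional GROMACS criteria (donor–acceptor distance ≤ 0.35 nm,
  hydrogen–donor–acceptor angle ≤ 30°).

Series are aggregated into mean/SD summaries and scanned for a plateau
onset: the earliest time from which every sliding window is both flat
(small least-squares slope) and quiet (small standard deviation), read as
the trajectory having reached a stationary conformational regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .nucleic import (
    ATOMIC_MASSES,
    AptadnaError,
    GeometryError,
    UnitsError,
    Structure,
    Trajectory,
)

logger = logging.getLogger("aptadna")

ANGSTROM_TO_NM = 0.1

# --------------------------------------------------------------------------
# Series containers
# --------------------------------------------------------------------------


@dataclass
class TimeSeries:
    """Per-frame descriptor values: times in ns, strictly increasing."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.units in ("nm", "angstrom") and np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label: {self.label}\n")
            fh.write(f"# units: {self.units}\n")
            fh.write("# time_ns\tvalue\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.6f}\t{v:.6f}\n")

    @classmethod
    def from_tsv(cls, path) -> "TimeSeries":
        label = units = ""
        times, values = [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("label:"):
                        label = body[6:].strip()
                    elif body.startswith("units:"):
                        units = body[6:].strip()
                    continue
                if not line.strip():
                    continue
                t, v = line.split("\t")
                times.append(float(t))
                values.append(float(v))
        return cls(np.array(times), np.array(values), label, units)


@dataclass
class SeriesSummary:
    """Mean / sample SD / frame count of one descriptor series."""

    mean: float
    sd: float
    n: int
    label: str = ""
    units: str = ""

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")


@dataclass
class PlateauResult:
    """Outcome of plateau-onset detection on one series."""

    onset_time: float | None
    window: float
    slope_tol: float
    fluctuation_tol: float


# --------------------------------------------------------------------------
# Kabsch superposition
# --------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal weighted rigid superposition of *mobile* onto *reference*.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD to
    *reference*.  Reflections are excluded by the determinant correction, so
    the rotation is always proper.  The RMSD is in the length units of the
    inputs.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("mobile and reference must be matching N×3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"superposition needs at least 3 atoms, got {n}")
    if weights is None:
        w = np.full(n, 1.0)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w <= 0):
            raise GeometryError("weights must be positive, one per atom")
    wsum = w.sum()

    mob_center = (w[:, None] * mobile).sum(axis=0) / wsum
    ref_center = (w[:, None] * reference).sum(axis=0) / wsum
    mob_c = mobile - mob_center
    ref_c = reference - ref_center

    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) coordinates")

    h = (w[:, None] * mob_c).T @ ref_c
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref_center - rotation @ mob_center

    diff = mob_c @ rotation.T - ref_c
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum() / wsum))
    return rotation, translation, rmsd


# --------------------------------------------------------------------------
# Atom selections
# --------------------------------------------------------------------------

_BACKBONE_NAMES = {
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'",
    "O2'", "C1'",
}

SELECTIONS = {
    "all": lambda atom, res: True,
    "heavy": lambda atom, res: atom.element != "H",
    "backbone": lambda atom, res: atom.name in _BACKBONE_NAMES,
    "base": lambda atom, res: atom.name not in _BACKBONE_NAMES
    and atom.element != "H",
}


def _selection_mask(s: Structure, selection) -> np.ndarray:
    if selection is None:
        selection = SELECTIONS["all"]
    elif isinstance(selection, str):
        try:
            selection = SELECTIONS[selection]
        except KeyError:
            raise AptadnaError(
                f"unknown selection {selection!r}; choose from "
                f"{sorted(SELECTIONS)}"
            ) from None
    mask = np.array(
        [selection(a, r) for r in s.residues for a in r.atoms], dtype=bool
    )
    return mask


# --------------------------------------------------------------------------
# RMSD series
# --------------------------------------------------------------------------


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    selection=None,
    mass_weighted: bool = True,
    label: str = "",
) -> TimeSeries:
    """Per-frame superposition RMSD of a trajectory against a fixed reference.

    The selection (a named selection or an ``(atom, residue) -> bool``
    predicate) is applied to both the reference and the trajectory topology
    and must resolve to the same atom count, at least 3.  Output is in nm.
    """
    ref_mask = _selection_mask(reference, selection)
    top_mask = _selection_mask(traj.topology, selection)
    n_ref, n_top = int(ref_mask.sum()), int(top_mask.sum())
    if n_ref != n_top:
        raise AptadnaError(
            f"selection resolves to {n_ref} reference atoms but {n_top} "
            "trajectory atoms"
        )
    if n_ref < 3:
        raise AptadnaError(f"selection resolves to {n_ref} atoms; need ≥ 3")

    ref_coords = reference.coords()[ref_mask]
    weights = traj.topology.masses()[top_mask] if mass_weighted else None
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        _r, _t, rmsd = kabsch_superpose(
            frame.coords[top_mask], ref_coords, weights
        )
        values[i] = rmsd * ANGSTROM_TO_NM
    return TimeSeries(traj.times, values, label or "RMSD", units="nm")


# --------------------------------------------------------------------------
# Hydrogen bonds
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (GROMACS convention by default).

    A bond is counted when the donor–acceptor distance is at most
    ``max_da_dist`` (nm) and the hydrogen–donor–acceptor angle at most
    ``max_hda_angle`` (degrees).  Donors are N/O atoms with a covalently
    attached hydrogen; acceptors are any N/O.  ``heavy_only_mode`` is a
    proxy for hydrogen-free models: donor-capable N/O (per residue
    templates) within ``heavy_da_dist`` of an acceptor, no angle term; its
    counts are not comparable to hydrogen-aware counts.
    """

    max_da_dist: float = 0.35       # nm
    max_hda_angle: float = 30.0     # degrees
    heavy_only_mode: bool = False
    heavy_da_dist: float = 0.32     # nm

    def __post_init__(self):
        if self.max_da_dist <= 0 or self.heavy_da_dist <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not 0 < self.max_hda_angle <= 90:
            raise ValueError("max_hda_angle must lie in (0, 90] degrees")


_HEAVY_BOND_CUTOFF = 1.85   # Å: heavy–heavy covalent bond inference
_H_BOND_CUTOFF = 1.25       # Å: hydrogen attachment to its heavy atom


class _HBondEngine:
    """Topology-derived bookkeeping reused across frames of one trajectory."""

    def __init__(self, topology: Structure, criteria: HBondCriteria):
        self.criteria = criteria
        self.atoms = list(topology.atoms())
        self.elements = np.array([a.element for a in self.atoms])
        self.residue_of = np.array([
            i for i, r in enumerate(topology.residues) for _ in r.atoms
        ])
        coords = topology.coords()
        self._build_bond_graph(coords)
        self._classify(topology)

    def _build_bond_graph(self, coords: np.ndarray) -> None:
        n = len(self.atoms)
        heavy = np.where(self.elements != "H")[0]
        hydro = np.where(self.elements == "H")[0]
        neighbors: list[set[int]] = [set() for _ in range(n)]
        if len(heavy):
            tree = cKDTree(coords[heavy])
            for i_loc, j_loc in tree.query_pairs(_HEAVY_BOND_CUTOFF):
                i, j = int(heavy[i_loc]), int(heavy[j_loc])
                neighbors[i].add(j)
                neighbors[j].add(i)
        self.h_parent = {}
        if len(hydro) and len(heavy):
            tree = cKDTree(coords[heavy])
            dist, idx = tree.query(coords[hydro])
            for h_loc, (d, p_loc) in enumerate(zip(dist, idx)):
                if d <= _H_BOND_CUTOFF:
                    h, p = int(hydro[h_loc]), int(heavy[p_loc])
                    neighbors[h].add(p)
                    neighbors[p].add(h)
                    self.h_parent[h] = p
        self.neighbors = neighbors
        # Atoms within ≤2 covalent bonds are excluded as donor/acceptor pairs.
        self.excluded: list[set[int]] = []
        for i in range(n):
            near = set(neighbors[i])
            for j in neighbors[i]:
                near |= neighbors[j]
            near.add(i)
            self.excluded.append(near)

    def _classify(self, topology: Structure) -> None:
        from .convert import default_templates

        templates = default_templates()
        no_set = np.isin(self.elements, ("N", "O"))
        self.acceptors = np.where(no_set)[0]
        if self.criteria.heavy_only_mode:
            donors = []
            offset = 0
            for res in topology.residues:
                tpl = templates[res.name] if res.name in templates else None
                for k, a in enumerate(res.atoms):
                    i = offset + k
                    if not no_set[i]:
                        continue
                    if tpl is None or a.name in tpl.donors:
                        donors.append(i)
                offset += len(res.atoms)
            self.donors = np.array(donors, dtype=int)
            self.donor_hydrogens = {int(d): [] for d in self.donors}
        else:
            donor_hydrogens: dict[int, list[int]] = {}
            for h, p in self.h_parent.items():
                if no_set[p]:
                    donor_hydrogens.setdefault(p, []).append(h)
            self.donors = np.array(sorted(donor_hydrogens), dtype=int)
            self.donor_hydrogens = donor_hydrogens
        if len(self.donors) == 0 or len(self.acceptors) == 0:
            logger.warning("no hydrogen-bond donors or acceptors found")

    def find(self, coords: np.ndarray) -> list[tuple]:
        crit = self.criteria
        cutoff = (
            crit.heavy_da_dist if crit.heavy_only_mode else crit.max_da_dist
        ) / ANGSTROM_TO_NM  # nm → Å
        cos_min = np.cos(np.deg2rad(crit.max_hda_angle))
        if len(self.donors) == 0 or len(self.acceptors) == 0:
            return []
        acc_tree = cKDTree(coords[self.acceptors])
        bonds = []
        seen = set()
        for d in self.donors:
            d = int(d)
            for a_loc in acc_tree.query_ball_point(coords[d], cutoff):
                a = int(self.acceptors[a_loc])
                if a == d or a in self.excluded[d]:
                    continue
                if crit.heavy_only_mode:
                    key = (d, None, a)
                    if key not in seen:
                        seen.add(key)
                        bonds.append((self.atoms[d], None, self.atoms[a]))
                    continue
                da = coords[a] - coords[d]
                da /= np.linalg.norm(da)
                for h in self.donor_hydrogens[d]:
                    dh = coords[h] - coords[d]
                    dh /= np.linalg.norm(dh)
                    if float(dh @ da) >= cos_min:
                        key = (d, h, a)
                        if key not in seen:
                            seen.add(key)
                            bonds.append(
                                (self.atoms[d], self.atoms[h], self.atoms[a])
                            )
        return bonds


def find_hbonds(
    structure: Structure,
    criteria: HBondCriteria = HBondCriteria(),
    coords: np.ndarray | None = None,
) -> list[tuple]:
    """Detect intramolecular hydrogen bonds in one conformation.

    Returns deduplicated ``(donor, hydrogen, acceptor)`` atom triples
    (hydrogen is ``None`` in heavy-only mode).  Pairs separated by at most
    two covalent bonds are excluded.  *coords* overrides the structure's own
    coordinates (same atom order), which is how per-frame counting works.
    """
    engine = _HBondEngine(structure, criteria)
    return engine.find(
        structure.coords() if coords is None else np.asarray(coords, float)
    )


def hbond_series(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    label: str = "",
) -> TimeSeries:
    """Per-frame intramolecular hydrogen-bond count over a trajectory."""
    engine = _HBondEngine(traj.topology, criteria)
    counts = np.array(
        [len(engine.find(f.coords)) for f in traj.frames], dtype=float
    )
    return TimeSeries(traj.times, counts, label or "H-bonds", units="count")


# --------------------------------------------------------------------------
# Summaries and plateau detection
# --------------------------------------------------------------------------


def summarize(series: TimeSeries, discard_before: float = 0.0) -> SeriesSummary:
    """Arithmetic mean and sample SD over frames with time ≥ *discard_before*."""
    keep = series.times >= discard_before
    values = series.values[keep]
    if len(values) < 2:
        raise AptadnaError(
            f"need at least 2 frames after discarding t < {discard_before} ns, "
            f"have {len(values)}"
        )
    return SeriesSummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n=int(len(values)),
        label=series.label,
        units=series.units,
    )


def detect_plateau(
    series: TimeSeries,
    window: float = 20.0,
    slope_tol: float = 0.005,
    fluctuation_tol: float = 0.1,
) -> PlateauResult:
    """Earliest onset of a sustained flat, quiet regime.

    The onset is the earliest sample time *t* such that every sliding window
    of length *window* starting at or after *t* has least-squares slope
    magnitude ≤ *slope_tol* and sample SD ≤ *fluctuation_tol*.  ``None`` when
    no such time exists.  Requires the series to span at least 2×window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if series.span < 2 * window:
        raise AptadnaError(
            f"series spans {series.span:g} ns; plateau detection needs at "
            f"least {2 * window:g} ns (2×window)"
        )
    times, values = series.times, series.values
    t_last_start = times[-1] - window
    starts = np.where(times <= t_last_start)[0]
    passed = np.empty(len(starts), dtype=bool)
    for k, i in enumerate(starts):
        in_win = (times >= times[i]) & (times <= times[i] + window)
        t_w, v_w = times[in_win], values[in_win]
        if len(t_w) < 2:
            passed[k] = False
            continue
        slope = np.polyfit(t_w, v_w, 1)[0]
        passed[k] = (
            abs(float(slope)) <= slope_tol
            and float(v_w.std(ddof=1)) <= fluctuation_tol
        )
    onset = None
    # earliest start index from which every later window also passes
    ok_from_here = np.logical_and.accumulate(passed[::-1])[::-1]
    hits = np.where(ok_from_here)[0]
    if len(hits):
        onset = float(times[starts[hits[0]]])
    return PlateauResult(onset, window, slope_tol, fluctuation_tol)


# --------------------------------------------------------------------------
# Table-style comparison
# --------------------------------------------------------------------------

_RMSD_UNITS = {"nm", "angstrom"}


def compare_runs(summaries: list[SeriesSummary]) -> pd.DataFrame:
    """Arrange summaries into a molecule/temperature grid.

    Rows are summary labels (e.g. ``"A6 (300 K)"``); columns are H-bond
    mean/SD (count-united summaries) and RMSD mean/SD (length-united
    summaries).  Duplicate (label, descriptor) entries and mixed RMSD length
    units are errors.
    """
    if not summaries:
        raise AptadnaError("need at least one summary")
    rmsd_units = {s.units for s in summaries if s.units in _RMSD_UNITS}
    if len(rmsd_units) > 1:
        raise UnitsError(f"mixed RMSD units: {sorted(rmsd_units)}")
    rows: dict[str, dict[str, float]] = {}
    seen = set()
    for s in summaries:
        kind = "HB" if s.units == "count" else "RMSD"
        key = (s.label, kind)
        if key in seen:
            raise AptadnaError(f"duplicate label {s.label!r} for {kind}")
        seen.add(key)
        row = rows.setdefault(s.label, {})
        row[f"{kind} mean"] = s.mean
        row[f"{kind} SD"] = s.sd
    columns = ["HB mean", "HB SD", "RMSD mean", "RMSD SD"]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=[c for c in columns if c in df.columns])
    df.index.name = "label"
    return df
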