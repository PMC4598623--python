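"""File formats and provenance: colvars-style tables, path JSON, PDB groups.

Tabular data travels in a plain-text columnar dialect: ``#``-prefixed
header lines naming the columns, whitespace-separated numeric rows, first
column time.  Repeated identical headers mid-file (simulation restarts)
are tolerated.  All outputs carry a provenance header (tool version,
configuration hash, seeds).  PDB reading is minimal and read-only:
ATOM/HETATM coordinate extraction with (chain, residue range, atom name)
group selections.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cvspace import CVSpace
from .errors import InputError, ParseError
from .orientation import AtomGroupFrame
from .paths import StringPath
from .reweight import PMFGrid, PerturbedFreeEnergies
from .samples import SampleSet


@dataclass
class ColvarsTable:
    """A parsed colvars-style table: named columns of numeric rows."""

    columns: tuple[str, ...]
    data: np.ndarray  # (n_rows, n_cols)
    source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.columns = tuple(self.columns)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.columns):
            raise InputError("column count does not match data width")
        t = self.data[:, 0]
        if t.size > 1 and np.any(np.diff(t) <= 0):
            bad = t[1:][np.diff(t) <= 0][0]
            raise ParseError(f"time column not strictly increasing at t={bad}")

    @property
    def times(self) -> np.ndarray:
        return self.data[:, 0]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.data[:, self.columns.index(name)]
        except ValueError:
            raise InputError(f"no column '{name}' in {self.columns}") from None

    def to_sample_set(self, space: CVSpace | None = None, window: int = 0,
                      replica: int = 0) -> SampleSet:
        names = self.columns[1:]
        space = space or CVSpace(tuple(names))
        if space.names != tuple(names):
            raise InputError("space names do not match table columns")
        n = self.data.shape[0]
        return SampleSet(
            space=space,
            times=self.times,
            values=self.data[:, 1:],
            window=np.full(n, window, dtype=int),
            replica=np.full(n, replica, dtype=int),
        )


def read_colvars(path: str | Path) -> ColvarsTable:
    """Parse a colvars-style trajectory file.

    Header lines start with ``#``; the first header declares the columns.
    A repeated identical header mid-file (a restart) is skipped; a
    conflicting one is an error.  Rows must all have the declared width.
    """
    path = Path(path)
    columns: tuple[str, ...] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line.lstrip("#").split()
                if not fields or fields[0].startswith("provenance"):
                    continue
                if columns is None:
                    columns = tuple(fields)
                elif tuple(fields) != columns:
                    raise ParseError(
                        f"{path}:{lineno}: conflicting header {fields} "
                        f"vs {list(columns)}"
                    )
                continue
            vals = line.split()
            if columns is None:
                raise ParseError(f"{path}:{lineno}: data before any header")
            if len(vals) != len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(columns)} fields, "
                    f"got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if columns is None or not rows:
        raise ParseError(f"{path}: no data rows")
    return ColvarsTable(columns=columns, data=np.asarray(rows), source=str(path))


def provenance_header(seeds: dict | None = None, config: dict | None = None,
                      comment: str = "#") -> str:
    """Standard provenance block: version, config hash, seeds."""
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    lines = [f"{comment} provenance: mfepath {__version__} config={cfg_hash}"]
    if seeds:
        seed_str = " ".join(f"{k}={v}" for k, v in sorted(seeds.items()))
        lines.append(f"{comment} provenance-seeds: {seed_str}")
    return "\n".join(lines)


def write_colvars(table: ColvarsTable, path: str | Path,
                  seeds: dict | None = None, config: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seeds, config) + "\n")
        fh.write("# " + " ".join(table.columns) + "\n")
        np.savetxt(fh, table.data, fmt="%.17g", delimiter=" ")


def sample_set_to_tables(samples: SampleSet) -> dict[int, ColvarsTable]:
    """One table per window, columns = time + CV names + replica.

    In BEUS exactly one replica holds each window at any time, so sorting
    a window's samples by time yields a valid strictly-increasing table.
    """
    out = {}
    cols = ("time",) + samples.space.names + ("replica",)
    for w in np.unique(samples.window):
        m = samples.window == w
        data = np.column_stack(
            [samples.times[m], samples.values[m], samples.replica[m]]
        )
        data = data[np.argsort(data[:, 0], kind="stable")]
        out[int(w)] = ColvarsTable(columns=cols, data=data)
    return out


def tables_to_sample_set(tables: dict[int, ColvarsTable],
                         space: CVSpace | None = None) -> SampleSet:
    """Reassemble a window-labelled sample set from per-window tables."""
    parts = []
    for w, tab in sorted(tables.items()):
        names = [c for c in tab.columns if c not in ("time", "replica")]
        sp = space or CVSpace(tuple(names))
        vals = np.column_stack([tab.column(c) for c in names])
        n = vals.shape[0]
        rep = (tab.column("replica").astype(int) if "replica" in tab.columns
               else np.full(n, w, dtype=int))
        parts.append((tab.times, vals, np.full(n, w, dtype=int), rep, sp))
    sp = parts[0][4]
    times = np.concatenate([p[0] for p in parts])
    vals = np.concatenate([p[1] for p in parts])
    wins = np.concatenate([p[2] for p in parts])
    reps = np.concatenate([p[3] for p in parts])
    order = np.lexsort((times, reps))
    return SampleSet(space=sp, times=times[order], values=vals[order],
                     window=wins[order], replica=reps[order])


def write_string_path(path_obj: StringPath, path: str | Path,
                      seeds: dict | None = None) -> None:
    """Lossless JSON round-trip of a string path."""
    payload = {
        "provenance": provenance_header(seeds, comment="").strip(),
        "names": list(path_obj.space.names),
        "scales": path_obj.space.scales.tolist(),
        "cyclic": path_obj.cyclic,
        "centers": [[float(x) for x in row] for row in path_obj.centers],
        "metadata": path_obj.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_string_path(path: str | Path) -> StringPath:
    payload = json.loads(Path(path).read_text())
    space = CVSpace(tuple(payload["names"]), np.asarray(payload["scales"]))
    return StringPath(
        np.asarray(payload["centers"], dtype=float),
        cyclic=bool(payload["cyclic"]),
        space=space,
        metadata=payload.get("metadata", {}),
    )


def write_free_energies(f: PerturbedFreeEnergies, path: str | Path,
                        errors: np.ndarray | None = None,
                        seeds: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seeds) + "\n")
        fh.write(f"# anchored F_0 = 0; beta = {f.beta}\n")
        if errors is None:
            fh.write("# image F\n")
            for i, v in enumerate(f.f):
                fh.write(f"{i} {v:.17g}\n")
        else:
            fh.write("# image F err\n")
            for i, (v, e) in enumerate(zip(f.f, errors)):
                fh.write(f"{i} {v:.17g} {e:.17g}\n")


def write_pmf(pmf: PMFGrid, path: str | Path, seeds: dict | None = None) -> None:
    """PMF TSV: bin centers, G (min 0), effective occupancy, mask flag."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seeds) + "\n")
        if pmf.ndim == 1:
            fh.write("# xi G occupancy masked\n")
            for c, g, o, m in zip(pmf.centers[0], pmf.g, pmf.occupancy, pmf.mask):
                gtxt = "nan" if m else f"{g:.17g}"
                fh.write(f"{c:.17g} {gtxt} {o:.17g} {int(m)}\n")
        else:
            fh.write("# xi1 xi2 G occupancy masked\n")
            for i, c1 in enumerate(pmf.centers[0]):
                for j, c2 in enumerate(pmf.centers[1]):
                    m = pmf.mask[i, j]
                    gtxt = "nan" if m else f"{pmf.g[i, j]:.17g}"
                    fh.write(
                        f"{c1:.17g} {c2:.17g} {gtxt} "
                        f"{pmf.occupancy[i, j]:.17g} {int(m)}\n"
                    )


def read_pdb_groups(pdb_path: str | Path, groups: dict) -> dict[str, AtomGroupFrame]:
    """Extract named atom groups from a PDB file.

    ``groups`` maps a group label to a selection dict with keys ``chain``,
    ``resid_start``, ``resid_stop`` (inclusive) and ``name`` (atom name,
    e.g. ``CA``).  Only ATOM/HETATM records are considered; coordinates in
    angstrom; atoms ordered by residue number (N-to-C for a helix).
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "PDB reading requires MDAnalysis (install extra 'pdb')"
        ) from exc
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb_path))
    out = {}
    for label, sel in groups.items():
        try:
            chain = sel["chain"]
            lo, hi = int(sel["resid_start"]), int(sel["resid_stop"])
            name = sel["name"]
        except KeyError as exc:
            raise InputError(f"group '{label}' missing key {exc}") from None
        ag = u.select_atoms(
            f"(chainID {chain} or segid {chain}) and resid {lo}:{hi} "
            f"and name {name}"
        )
        if ag.n_atoms == 0:
            raise InputError(f"group '{label}': selection matched no atoms")
        order = np.argsort(ag.resids, kind="stable")
        out[label] = AtomGroupFrame(label=label, coords=ag.positions[order])
    return out
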