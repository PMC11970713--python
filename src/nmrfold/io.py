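"""Domain types and file I/O for shifts, peaks, dihedral predictions and ensembles.

The canonical on-disk formats are deliberately plain text:

* shift tables — TSV with named columns
  ``residue_index  residue_type  atom  nucleus  shift_ppm  form``
  (``nucleus`` and ``form`` optional; a reduced NMR-STAR reader is provided
  as a convenience for BMRB-style deposition files);
* peak lists — Sparky ``.list`` style or TSV;
* dihedral predictions — TALOS-style whitespace tables (``VARS``/``FORMAT``
  header lines, one row per residue with PHI/PSI/DPHI/DPSI/CLASS);
* coordinates — standard multi-model PDB, written and read through gemmi.

Residue numbering is the construct numbering (1-based) everywhere.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi

log = logging.getLogger(__name__)

NUCLEI = ("H", "HN", "N", "C", "Cprime")

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}

#: common legacy / alternative atom labels normalized to the package convention
ATOM_ALIASES = {
    "H": "HN",      # amide proton is HN here
    "HT": "HN",
    "CO": "C",
    "C'": "C",
}


def normalize_atom_name(name: str, aliases: dict | None = None) -> str:
    table = ATOM_ALIASES if aliases is None else aliases
    return table.get(name.strip().upper(), name.strip().upper())


def infer_nucleus(atom_name: str) -> str:
    """Nucleus category for an atom label: HN, H, N, C or Cprime."""
    a = atom_name.upper()
    if a == "HN":
        return "HN"
    if a == "N" or (a.startswith("N") and a not in AA3):
        return "N"
    if a == "C":
        return "Cprime"
    if a.startswith("H") or a.startswith("Q"):  # Q* = pseudo protons
        return "H"
    if a.startswith("C"):
        return "C"
    raise ValueError(f"cannot infer nucleus for atom {atom_name!r}")


@dataclass(frozen=True)
class ShiftEntry:
    residue_index: int
    residue_type: str
    atom_name: str
    nucleus: str
    shift: float
    form: str = "S"

    def __post_init__(self):
        if self.nucleus not in NUCLEI:
            raise ValueError(f"unknown nucleus {self.nucleus!r}")
        if self.form not in ("S", "U"):
            raise ValueError(f"form must be 'S' or 'U', got {self.form!r}")
        if not math.isfinite(self.shift):
            raise ValueError(f"non-finite shift for {self.key}")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.residue_index, self.atom_name, self.form)


class ShiftTable:
    """Assigned chemical shifts, unique per (residue, atom, form)."""

    def __init__(self, entries: Iterable[ShiftEntry] = ()):
        self._entries: dict[tuple[int, str, str], ShiftEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: ShiftEntry) -> None:
        if entry.key in self._entries:
            raise ValueError(
                f"duplicate shift entry for residue {entry.residue_index} "
                f"atom {entry.atom_name} form {entry.form}"
            )
        self._entries[entry.key] = entry

    def get(self, residue_index: int, atom_name: str, form: str = "S") -> ShiftEntry | None:
        return self._entries.get((residue_index, atom_name, form))

    def __iter__(self) -> Iterator[ShiftEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def residues(self, form: str | None = None) -> list[int]:
        rs = {e.residue_index for e in self if form is None or e.form == form}
        return sorted(rs)

    def atoms_of(self, residue_index: int, form: str | None = None) -> list[ShiftEntry]:
        return [
            e for e in self
            if e.residue_index == residue_index and (form is None or e.form == form)
        ]

    def by_nucleus(self, nuclei: Sequence[str], form: str | None = None) -> list[ShiftEntry]:
        return [
            e for e in self
            if e.nucleus in nuclei and (form is None or e.form == form)
        ]


@dataclass(frozen=True)
class Peak:
    peak_id: str
    dims: tuple[str, ...]
    position: tuple[float, ...]
    intensity: float

    def __post_init__(self):
        if len(self.position) != len(self.dims):
            raise ValueError(
                f"peak {self.peak_id}: {len(self.position)} positions for "
                f"{len(self.dims)} dimensions"
            )
        if not self.intensity > 0:
            raise ValueError(f"peak {self.peak_id}: intensity must be > 0")


class PeakList:
    def __init__(self, peaks: Iterable[Peak] = ()):
        self._peaks: list[Peak] = []
        self._by_id: dict[str, Peak] = {}
        for p in peaks:
            self.add(p)

    def add(self, peak: Peak) -> None:
        if peak.peak_id in self._by_id:
            raise ValueError(f"duplicate peak id {peak.peak_id!r}")
        self._peaks.append(peak)
        self._by_id[peak.peak_id] = peak

    def __iter__(self) -> Iterator[Peak]:
        return iter(self._peaks)

    def __len__(self) -> int:
        return len(self._peaks)

    def __getitem__(self, peak_id: str) -> Peak:
        return self._by_id[peak_id]

    def __contains__(self, peak_id: str) -> bool:
        return peak_id in self._by_id

    @property
    def dims(self) -> tuple[str, ...] | None:
        return self._peaks[0].dims if self._peaks else None


@dataclass
class TitrationSeries:
    """Ordered (metal:protein molar ratio, peak list) points; first is apo."""

    points: list[tuple[float, PeakList]]

    def __post_init__(self):
        if not self.points:
            raise ValueError("titration series is empty")
        ratios = [r for r, _ in self.points]
        if ratios[0] != 0:
            raise ValueError("first titration point must be the apo reference (ratio 0)")
        if any(b < a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("molar ratios must be nondecreasing")

    @property
    def ratios(self) -> list[float]:
        return [r for r, _ in self.points]


@dataclass(frozen=True)
class DihedralPrediction:
    residue_index: int
    angle_name: str  # phi | psi
    predicted_value: float  # degrees
    spread: float  # degrees
    classification: str

    def __post_init__(self):
        if self.angle_name not in ("phi", "psi"):
            raise ValueError(f"angle_name must be phi or psi, got {self.angle_name!r}")
        if not -180.0 <= self.predicted_value <= 180.0:
            raise ValueError(
                f"predicted angle {self.predicted_value} out of [-180, 180]"
            )
        if self.spread < 0:
            raise ValueError("spread must be >= 0")


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

_DEFAULT_DIMS = {2: ("HN", "N"), 3: ("H", "H", "N")}


def parse_peak_list(path, dialect: str = "sparky", dims: Sequence[str] | None = None) -> PeakList:
    """Read a peak list.

    ``dialect='sparky'``: Sparky ``.list`` layout — an optional header line
    (``Assignment  w1  w2  ...``), then one row per peak with an assignment
    label, one ppm per dimension and an intensity.  ``dialect='tsv'``: TSV
    with header ``peak_id <nuc1> <nuc2> ... intensity``.

    A comment line ``# dims: H H`` overrides the per-dimension nucleus labels;
    otherwise ``dims`` (or an HN/N-style default) is used.
    """
    path = Path(path)
    if dialect not in ("sparky", "tsv"):
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    text = path.read_text().splitlines()
    peaks = PeakList()
    file_dims = tuple(dims) if dims else None
    header_cols: list[str] | None = None
    n_auto = 0

    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*dims\s*:\s*(.+)", line)
            if m:
                file_dims = tuple(m.group(1).split())
            continue
        toks = line.split("\t") if dialect == "tsv" else line.split()
        if dialect == "tsv" and header_cols is None:
            header_cols = [t.strip() for t in toks]
            if header_cols[0] != "peak_id" or header_cols[-1] != "intensity":
                raise ValueError(
                    f"{path}:{lineno}: TSV peak header must be "
                    "'peak_id <nuclei...> intensity'"
                )
            if file_dims is None:
                file_dims = tuple(header_cols[1:-1])
            continue
        if dialect == "sparky" and ("Assignment" in toks or toks[0].lower() == "assignment"):
            continue
        try:
            if dialect == "tsv":
                label, values = toks[0], [float(t) for t in toks[1:]]
            else:
                label, values = toks[0], [float(t) for t in toks[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed peak row: {raw!r}") from exc
        if len(values) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=2 ppm values and an intensity")
        pos, inten = values[:-1], values[-1]
        use_dims = file_dims or _DEFAULT_DIMS.get(len(pos))
        if use_dims is None or len(use_dims) != len(pos):
            raise ValueError(
                f"{path}:{lineno}: cannot determine nuclei for {len(pos)}-D peak"
            )
        if inten < 0:
            log.debug("%s:%d: negative intensity folded to magnitude", path, lineno)
            inten = abs(inten)
        if inten == 0:
            raise ValueError(f"{path}:{lineno}: zero intensity")
        if label in ("?-?", "?-?-?", "?"):
            n_auto += 1
            label = f"peak{n_auto}"
        if label in peaks:
            n_auto += 1
            label = f"{label}.{n_auto}"
        peaks.add(Peak(label, tuple(use_dims), tuple(pos), inten))

    if len(peaks) == 0:
        warnings.warn(f"peak list {path} contains no peaks", stacklevel=2)
    return peaks


def write_peak_list(peaks: PeakList, path, dialect: str = "sparky") -> None:
    path = Path(path)
    lines = []
    if dialect == "sparky":
        current_dims = None
        for p in peaks:
            if p.dims != current_dims:
                current_dims = p.dims
                lines.append("# dims: " + " ".join(current_dims))
                lines.append("      Assignment " + " ".join(
                    f"w{i+1}" for i in range(len(current_dims))) + "  Data Height")
            lines.append(
                f"{p.peak_id:>16s} "
                + " ".join(f"{x:9.3f}" for x in p.position)
                + f"  {p.intensity:.6e}"
            )
    elif dialect == "tsv":
        dims = peaks.dims or ()
        if any(p.dims != dims for p in peaks):
            raise ValueError("TSV peak lists require uniform dimensionality; "
                             "use the sparky dialect for mixed lists")
        lines.append("\t".join(["peak_id", *dims, "intensity"]))
        for p in peaks:
            lines.append("\t".join(
                [p.peak_id, *(f"{x:.3f}" for x in p.position), f"{p.intensity:.6e}"]
            ))
    else:
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# shift tables
# ---------------------------------------------------------------------------

def parse_shift_table(path) -> ShiftTable:
    """Read the canonical TSV shift table (see module docstring)."""
    path = Path(path)
    rows = path.read_text().splitlines()
    header: list[str] | None = None
    table = ShiftTable()
    for lineno, raw in enumerate(rows, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        toks = [t.strip() for t in re.split(r"\t|\s{2,}|\s", line) if t.strip()]
        if header is None:
            header = [t.lower() for t in toks]
            required = {"residue_index", "residue_type", "atom", "shift_ppm"}
            if not required.issubset(header):
                raise ValueError(f"{path}: shift table header missing {required - set(header)}")
            if "form" not in header:
                log.info("%s: no form column; defaulting all entries to form S", path)
            continue
        rec = dict(zip(header, toks))
        try:
            atom = normalize_atom_name(rec["atom"])
            entry = ShiftEntry(
                residue_index=int(rec["residue_index"]),
                residue_type=rec["residue_type"].upper(),
                atom_name=atom,
                nucleus=rec.get("nucleus") or infer_nucleus(atom),
                shift=float(rec["shift_ppm"]),
                form=rec.get("form", "S"),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: bad shift row {raw!r}: {exc}") from exc
        try:
            table.add(entry)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return table


def write_shift_table(table: ShiftTable, path) -> None:
    path = Path(path)
    lines = ["residue_index\tresidue_type\tatom\tnucleus\tshift_ppm\tform"]
    for e in sorted(table, key=lambda e: (e.form, e.residue_index, e.atom_name)):
        lines.append(
            f"{e.residue_index}\t{e.residue_type}\t{e.atom_name}\t{e.nucleus}"
            f"\t{e.shift:.3f}\t{e.form}"
        )
    path.write_text("\n".join(lines) + "\n")


def parse_shift_star(path, form: str = "S", aliases: dict | None = None) -> ShiftTable:
    """Reduced NMR-STAR reader: pulls the ``_Atom_chem_shift`` loop only.

    Convenience for BMRB-style files; the TSV reader is canonical.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    tags: list[str] = []
    table = ShiftTable()
    in_loop = False
    reading = False
    for raw in lines:
        line = raw.strip()
        if line == "loop_":
            in_loop, reading, tags = True, False, []
            continue
        if in_loop and line.startswith("_"):
            tags.append(line.split(".")[-1] if "." in line else line[1:])
            continue
        if in_loop and line == "stop_":
            in_loop = reading = False
            continue
        if in_loop and tags and line and not line.startswith("_"):
            reading = True
        if reading and line:
            if not any(t in tags for t in ("Val", "Chem_shift_value")):
                reading = in_loop = False
                continue
            toks = line.split()
            if len(toks) != len(tags):
                continue
            rec = dict(zip(tags, toks))
            seq = rec.get("Seq_ID") or rec.get("Comp_index_ID")
            comp = rec.get("Comp_ID", "XXX")
            atom = rec.get("Atom_ID")
            val = rec.get("Val") or rec.get("Chem_shift_value")
            if seq is None or atom is None or val is None:
                continue
            atom = normalize_atom_name(atom, aliases)
            table.add(ShiftEntry(
                residue_index=int(seq),
                residue_type=AA1.get(comp.upper(), "X"),
                atom_name=atom,
                nucleus=infer_nucleus(atom),
                shift=float(val),
                form=form,
            ))
    return table


# ---------------------------------------------------------------------------
# dihedral predictions
# ---------------------------------------------------------------------------

_TALOS_MISSING = 9999.0


def parse_dihedral_predictions(path) -> list[DihedralPrediction]:
    """Read a TALOS-style prediction table (VARS/FORMAT header, one row/residue)."""
    path = Path(path)
    varnames: list[str] | None = None
    out: list[DihedralPrediction] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("REMARK", "DATA", "FORMAT", "#")):
            continue
        if line.startswith("VARS"):
            varnames = line.split()[1:]
            continue
        if varnames is None:
            raise ValueError(f"{path}:{lineno}: missing VARS header line")
        for col in ("PHI", "PSI", "DPHI", "DPSI", "CLASS"):
            if col not in varnames:
                raise ValueError(f"{path}: prediction table lacks required column {col}")
        toks = line.split()
        if len(toks) != len(varnames):
            raise ValueError(f"{path}:{lineno}: {len(toks)} fields for {len(varnames)} VARS")
        rec = dict(zip(varnames, toks))
        try:
            resid = int(rec["RESID"])
            for angle, dcol in (("phi", "DPHI"), ("psi", "DPSI")):
                val = float(rec[angle.upper()])
                spread = float(rec[dcol])
                if abs(val) >= _TALOS_MISSING:
                    continue
                out.append(DihedralPrediction(resid, angle, val, spread, rec["CLASS"]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad prediction row: {exc}") from exc
    return out


def write_dihedral_predictions(preds: Sequence[DihedralPrediction], path) -> None:
    by_res: dict[int, dict] = {}
    for p in preds:
        d = by_res.setdefault(p.residue_index, {"CLASS": p.classification})
        d[p.angle_name] = (p.predicted_value, p.spread)
    lines = [
        "VARS RESID RESNAME PHI PSI DPHI DPSI CLASS",
        "FORMAT %4d %s %8.3f %8.3f %8.3f %8.3f %s",
    ]
    for resid in sorted(by_res):
        d = by_res[resid]
        phi, dphi = d.get("phi", (_TALOS_MISSING, 0.0))
        psi, dpsi = d.get("psi", (_TALOS_MISSING, 0.0))
        lines.append(
            f"{resid:4d} X {phi:8.3f} {psi:8.3f} {dphi:8.3f} {dpsi:8.3f} {d['CLASS']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coordinate ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """Flat atom description used when writing/reading PDB ensembles."""

    residue_index: int
    residue_type: str  # one-letter, or 'AG' for the metal
    atom_name: str
    element: str
    hetatm: bool = False


def write_ensemble(models: Sequence, atoms: Sequence[AtomRecord], path) -> None:
    """Write coordinates as a multi-model PDB (MODEL/ENDMDL), metal as HETATM."""
    import numpy as np

    if len(models) == 0:
        raise ValueError("empty model list")
    n_atoms = len(atoms)
    for k, m in enumerate(models):
        arr = np.asarray(m, dtype=float)
        if arr.shape != (n_atoms, 3):
            raise ValueError(
                f"model {k}: expected {n_atoms} atoms with xyz, got shape {arr.shape}"
            )

    st = gemmi.Structure()
    st.name = "nmrfold ensemble"
    for k, m in enumerate(models, start=1):
        arr = np.asarray(m, dtype=float)
        model = gemmi.Model(str(k))
        chain = gemmi.Chain("A")
        res_by_idx: dict[int, gemmi.Residue] = {}
        res_order: list[int] = []
        for a, xyz in zip(atoms, arr):
            res = res_by_idx.get(a.residue_index)
            if res is None:
                res = gemmi.Residue()
                res.name = AA3.get(a.residue_type, a.residue_type.upper())
                res.seqid = gemmi.SeqId(a.residue_index, " ")
                res.het_flag = "H" if a.hetatm else "A"
                res_by_idx[a.residue_index] = res
                res_order.append(a.residue_index)
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.element = gemmi.Element(a.element)
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
        for idx in res_order:
            chain.add_residue(res_by_idx[idx])
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc_path = str(Path(path))
    st.write_pdb(doc_path)


def read_ensemble(path):
    """Read a multi-model PDB back as (list of (n_atoms, 3) arrays, [AtomRecord])."""
    import numpy as np

    st = gemmi.read_structure(str(Path(path)))
    models = []
    atoms: list[AtomRecord] | None = None
    for model in st:
        coords = []
        recs = []
        for chain in model:
            for res in chain:
                one = AA1.get(res.name, res.name)
                het = res.het_flag == "H"
                for atom in res:
                    recs.append(AtomRecord(
                        res.seqid.num, one, atom.name, atom.element.name.upper(), het,
                    ))
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        arr = np.asarray(coords, dtype=float)
        if atoms is None:
            atoms = recs
        elif len(recs) != len(atoms):
            raise ValueError("inconsistent atom counts across models")
        models.append(arr)
    return models, atoms or []
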