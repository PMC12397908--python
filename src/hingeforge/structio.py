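"""Macromolecular structure I/O and Cα-trace extraction.

Structures are read from PDB or mmCIF files into a flat :class:`StructureModel`
(a list of atom records in author order).  Alternative locations are collapsed
to a single conformer (highest occupancy, ties broken alphabetically) so that
all downstream geometry is single-valued.  Waters are dropped by default;
other heteroatoms (cofactors such as FAD, nucleotide analogues such as
GppNHp) are kept because cofactor atoms take part in distance measurements.

Residue identity is the author numbering (number + insertion code), which is
how residues are cited in the structural literature (e.g. N118, K454).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Valid span of a consecutive Cα–Cα distance in an unbroken chain, Å.
CA_CA_RANGE = (2.5, 4.5)

#: Largest coordinate magnitude representable in the PDB %8.3f field.
PDB_COORD_LIMIT = 9999.999


class StructureError(Exception):
    """Base class for structure I/O errors."""


class StructureParseError(StructureError):
    """A file could not be parsed under the requested dialect."""


class StructureFormatError(StructureError):
    """Unknown or unsupported file format."""


class SelectionError(StructureError):
    """An atom or residue selection resolved to zero or multiple atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom, in author numbering."""

    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""
    hetero: bool = False

    def key(self) -> tuple:
        return (self.chain, self.resnum, self.icode, self.name, self.altloc)

    def residue_id(self) -> tuple:
        return (self.chain, self.resnum, self.icode)


@dataclass
class StructureModel:
    """Flat, ordered collection of atom records for one model."""

    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        for a in self.atoms:
            if not np.all(np.isfinite(a.coords)):
                raise StructureError(f"non-finite coordinates for atom {a.key()}")
            k = a.key()
            if k in seen:
                raise StructureError(f"duplicate atom record {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def chain_atoms(self, chain: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain == chain]

    def subset(self, chains: Iterable[str]) -> "StructureModel":
        chains = set(chains)
        return StructureModel([a for a in self.atoms if a.chain in chains])

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack([a.coords for a in self.atoms])


@dataclass
class CaTrace:
    """Ordered Cα coordinates of one chain (or selection thereof).

    ``has_breaks`` flags traces whose consecutive Cα–Cα distances fall
    outside the physical 2.5–4.5 Å range, e.g. because of unmodelled loops
    or a deliberately relocated segment.
    """

    chain_id: str
    residue_numbers: np.ndarray  # (N,) int
    residue_names: np.ndarray  # (N,) str
    coords: np.ndarray  # (N, 3) float, Å
    icodes: np.ndarray | None = None
    has_breaks: bool = False

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("CaTrace coords must be N×3")
        n = len(self.residue_numbers)
        if n < 2:
            raise StructureError("CaTrace needs at least 2 residues")
        if self.coords.shape[0] != n or len(self.residue_names) != n:
            raise StructureError("CaTrace field lengths disagree")
        if len(np.unique(self.residue_numbers)) != n and self.icodes is None:
            raise StructureError("duplicate residue numbers in CaTrace")
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        lo, hi = CA_CA_RANGE
        if np.any((d < lo) | (d > hi)):
            self.has_breaks = True

    def __len__(self) -> int:
        return self.coords.shape[0]

    def index_of(self, resnum: int) -> int:
        idx = np.flatnonzero(self.residue_numbers == resnum)
        if idx.size != 1:
            raise SelectionError(
                f"residue {resnum} matches {idx.size} positions in chain {self.chain_id}"
            )
        return int(idx[0])

    def select(self, residue_numbers: Sequence[int]) -> "CaTrace":
        """Sub-trace over the given residue numbers (trace order kept)."""
        wanted = set(int(r) for r in residue_numbers)
        mask = np.array([int(r) in wanted for r in self.residue_numbers])
        if mask.sum() < 2:
            raise SelectionError("selection leaves fewer than 2 residues")
        return CaTrace(
            chain_id=self.chain_id,
            residue_numbers=self.residue_numbers[mask],
            residue_names=self.residue_names[mask],
            coords=self.coords[mask],
            icodes=None if self.icodes is None else self.icodes[mask],
        )

    def with_coords(self, coords: np.ndarray) -> "CaTrace":
        return CaTrace(
            chain_id=self.chain_id,
            residue_numbers=self.residue_numbers.copy(),
            residue_names=self.residue_names.copy(),
            coords=np.asarray(coords, dtype=float).copy(),
            icodes=None if self.icodes is None else self.icodes.copy(),
        )


@dataclass(frozen=True)
class AtomSelector:
    """Addresses exactly one atom: chain + residue number + atom name.

    ``resname`` narrows the match to a residue name (useful for cofactors,
    e.g. ``AtomSelector("C", 701, "N5", resname="FAD")``); ``altloc``
    disambiguates alternative locations if any survived reading.
    """

    chain: str
    resnum: int
    atom_name: str
    resname: str | None = None
    altloc: str | None = None

    def matches(self, a: AtomRecord) -> bool:
        if a.chain != self.chain or a.resnum != self.resnum:
            return False
        if a.name != self.atom_name:
            return False
        if self.resname is not None and a.resname != self.resname:
            return False
        if self.altloc is not None and a.altloc != self.altloc:
            return False
        return True


def _detect_format(path: Path, fmt: str) -> gemmi.CoorFormat:
    fmt = fmt.lower()
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt in ("mmcif", "cif"):
        return gemmi.CoorFormat.Mmcif
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".cif", ".mmcif"):
            return gemmi.CoorFormat.Mmcif
        if suffix in (".pdb", ".ent"):
            return gemmi.CoorFormat.Pdb
        return gemmi.CoorFormat.Detect
    raise StructureFormatError(f"unknown structure format {fmt!r}")


def _prune_altlocs(records: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one altloc per atom site: highest occupancy, ties alphabetical."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in records:
        site = (a.chain, a.resnum, a.icode, a.name)
        if site not in best:
            best[site] = a
            order.append(site)
        else:
            b = best[site]
            if (a.occupancy, _altloc_rank(a.altloc)) > (
                b.occupancy,
                _altloc_rank(b.altloc),
            ):
                best[site] = a
    return [replace(best[s], altloc="") for s in order]


def _altloc_rank(altloc: str) -> float:
    # higher is better; '' beats 'A' beats 'B' ...
    if altloc == "":
        return 0.0
    return -ord(altloc[0])


def read_structure(
    path: str | Path,
    format: str = "auto",
    drop_waters: bool = True,
    model_index: int = 0,
) -> StructureModel:
    """Read a PDB/mmCIF file into a :class:`StructureModel`.

    Only one model (by default the first) is kept.  Alternative locations
    are collapsed to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    coor_format = _detect_format(path, format)
    try:
        st = gemmi.read_structure(str(path), format=coor_format)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        return StructureModel([])
    model = st[model_index]
    records: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if drop_waters and res.name in WATER_NAMES:
                continue
            for atom in res:
                altloc = atom.altloc if atom.altloc != "\x00" else ""
                records.append(
                    AtomRecord(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        resname=res.name,
                        name=atom.name,
                        element=atom.element.name.upper(),
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        altloc=altloc,
                        hetero=res.het_flag == "H",
                    )
                )
    records = _prune_altlocs(records)
    return StructureModel(records)


def write_structure(model: StructureModel, path: str | Path, format: str = "pdb") -> None:
    """Write a :class:`StructureModel` as a PDB file.

    Coordinates outside the fixed-width PDB field (|x| > 9999.999 Å) are
    rejected rather than silently mangled.
    """
    if format.lower() != "pdb":
        raise StructureFormatError(f"unsupported output format {format!r}")
    for a in model.atoms:
        if np.any(np.abs(a.coords) > PDB_COORD_LIMIT):
            raise StructureError(
                f"coordinates of atom {a.key()} exceed the PDB fixed-width range"
            )
    st = _to_gemmi(model)
    st.write_pdb(str(path))


def _to_gemmi(model: StructureModel, model_name: str = "1") -> gemmi.Structure:
    # gemmi's add_residue/add_chain copy their argument, so every container
    # must be fully populated before it is added to its parent
    by_chain: dict[str, list[tuple]] = {}
    res_order: dict[str, list[tuple]] = {}
    grouped: dict[tuple, list[AtomRecord]] = {}
    for a in model.atoms:
        rid = a.residue_id()
        if a.chain not in by_chain:
            by_chain[a.chain] = []
            res_order[a.chain] = []
        if rid not in grouped:
            grouped[rid] = []
            res_order[a.chain].append(rid)
        grouped[rid].append(a)

    st = gemmi.Structure()
    gm = gemmi.Model(model_name)
    for chain_name, rids in res_order.items():
        ch = gemmi.Chain(chain_name)
        for rid in rids:
            first = grouped[rid][0]
            res = gemmi.Residue()
            res.name = first.resname
            res.seqid = gemmi.SeqId(first.resnum, first.icode if first.icode else " ")
            res.het_flag = "H" if first.hetero else "A"
            for a in grouped[rid]:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.pos = gemmi.Position(*a.coords)
                atom.occ = a.occupancy
                atom.element = gemmi.Element(a.element.capitalize())
                if a.altloc:
                    atom.altloc = a.altloc
                res.add_atom(atom)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_trajectory(traces: Sequence[CaTrace], path: str | Path) -> None:
    """Write a list of Cα traces as a multi-MODEL PDB trajectory."""
    st = gemmi.Structure()
    for i, trace in enumerate(traces, start=1):
        gm = gemmi.Model(str(i))
        ch = gemmi.Chain(trace.chain_id or "A")
        for resnum, resname, xyz in zip(
            trace.residue_numbers, trace.residue_names, trace.coords
        ):
            res = gemmi.Residue()
            res.name = str(resname)
            res.seqid = gemmi.SeqId(int(resnum), " ")
            res.het_flag = "A"
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
            ch.add_residue(res)
        gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def extract_ca_trace(
    model: StructureModel,
    chain: str,
    residue_range: tuple[int, int] | None = None,
) -> CaTrace:
    """Extract the Cα trace of one chain, in author order.

    Residues lacking a Cα atom (e.g. cofactors, incompletely modelled
    residues) are skipped with a logged warning.
    """
    atoms = model.chain_atoms(chain)
    if not atoms:
        raise SelectionError(
            f"chain {chain!r} not found; available: {model.chains}"
        )
    # group by residue in author order
    residues: dict[tuple, list[AtomRecord]] = {}
    order: list[tuple] = []
    for a in atoms:
        rid = a.residue_id()
        if residue_range is not None and not (
            residue_range[0] <= a.resnum <= residue_range[1]
        ):
            continue
        if rid not in residues:
            residues[rid] = []
            order.append(rid)
        residues[rid].append(a)
    if not order:
        raise SelectionError(
            f"empty selection: chain {chain!r}, range {residue_range}"
        )
    nums, names, icodes, coords = [], [], [], []
    for rid in order:
        # calcium ions also carry atom name CA but element Ca; a true Cα is carbon
        ca = [a for a in residues[rid] if a.name == "CA" and a.element != "CA"]
        if not ca:
            if not all(a.hetero for a in residues[rid]):
                logger.warning(
                    "residue %s %s%s has no CA atom; skipped",
                    residues[rid][0].resname,
                    rid[1],
                    rid[2],
                )
            continue
        a = ca[0]
        nums.append(a.resnum)
        names.append(a.resname)
        icodes.append(a.icode)
        coords.append(a.coords)
    if len(nums) < 2:
        raise SelectionError(
            f"chain {chain!r} has fewer than 2 Cα atoms in range {residue_range}"
        )
    return CaTrace(
        chain_id=chain,
        residue_numbers=np.array(nums, dtype=int),
        residue_names=np.array(names, dtype=object),
        coords=np.stack(coords),
        icodes=np.array(icodes, dtype=object),
    )


def resolve_atom(model: StructureModel, sel: AtomSelector) -> np.ndarray:
    """Resolve a selector to the coordinates of exactly one atom."""
    hits = [a for a in model.atoms if sel.matches(a)]
    if len(hits) == 1:
        return hits[0].coords.copy()
    if not hits:
        raise SelectionError(f"selector {sel} matches no atom")
    listing = ", ".join(str(a.key()) for a in hits[:10])
    raise SelectionError(
        f"selector {sel} is ambiguous: {len(hits)} matches ({listing})"
    )
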