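"""Structure, shift-table and restraint I/O.

All coordinate handling goes through gemmi; this module converts between the
on-disk formats (PDB, mmCIF, TSV shift tables, CYANA ``.upl``/``.lol``) and
the package's light-weight in-memory types.

Residue numbers are taken verbatim from the coordinate file and mapped onto
full-length-protein numbering only through an explicit, user-supplied offset;
nothing is renumbered silently.
"""

from __future__ import annotations

import logging
import math
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AMINO_3TO1 = {v: k for k, v in AMINO_1TO3.items()}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed or yields no models."""


class ShiftTableError(ValueError):
    """Raised for malformed shift tables (duplicates, non-numeric shifts)."""


class RestraintError(ValueError):
    """Raised for inconsistent distance restraints (e.g. lower > upper)."""


@dataclass(frozen=True)
class Atom:
    """A single atom with coordinates in Angstrom."""

    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    xyz: tuple[float, float, float]

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError(f"non-finite coordinates for atom {self.key()}")

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.name)

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class Model:
    """One coordinate model: an ordered list of atoms, unique per (chain, residue, atom)."""

    model_id: int
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        keys = [a.key() for a in self.atoms]
        if len(keys) != len(set(keys)):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom {dup} in model {self.model_id}")

    def atom_index(self) -> dict[tuple[str, int, str], Atom]:
        return {a.key(): a for a in self.atoms}

    def residue_numbers(self) -> list[int]:
        return sorted({a.residue_number for a in self.atoms})

    def residue_names(self) -> dict[int, str]:
        return {a.residue_number: a.residue_name for a in self.atoms}

    def get(self, chain_id: str, residue_number: int, name: str) -> Atom | None:
        return self.atom_index().get((chain_id, residue_number, name))


@dataclass
class Ensemble:
    """A set of models sharing one (chain, residue, atom) skeleton."""

    models: list[Model]
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.models:
            raise StructureParseError("ensemble with zero models")

    def __len__(self) -> int:
        return len(self.models)


@dataclass
class ShiftTable:
    """Per-residue amide shifts for one experimental condition.

    ``data`` columns: residue_number (int), residue_type (1-letter),
    dH_ppm, dN_ppm (float, NaN allowed only for prolines).
    """

    condition_label: str
    data: pd.DataFrame
    temperature: float | None = None  # kelvin

    def __post_init__(self):
        df = self.data
        required = ["residue_number", "residue_type", "dH_ppm", "dN_ppm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ShiftTableError(f"shift table missing columns {missing}")
        if df["residue_number"].duplicated().any():
            dup = df.loc[df["residue_number"].duplicated(), "residue_number"].iloc[0]
            raise ShiftTableError(f"duplicate residue_number {dup}")
        non_pro = df["residue_type"] != "P"
        for col in ("dH_ppm", "dN_ppm"):
            bad = df.loc[non_pro, col]
            if bad.isna().any() or not np.isfinite(bad.dropna()).all():
                row = int(df.index[non_pro & ~np.isfinite(df[col])][0])
                raise ShiftTableError(
                    f"non-finite {col} at row {row} (residue "
                    f"{df.loc[row, 'residue_number']})"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def prolines(self) -> list[int]:
        return self.data.loc[self.data["residue_type"] == "P", "residue_number"].tolist()


@dataclass(frozen=True)
class RestraintAtom:
    residue_number: int
    residue_name: str
    atom_name: str


@dataclass(frozen=True)
class DistanceRestraint:
    """One CYANA-style distance bound between a donor-side and an acceptor-side atom."""

    donor: RestraintAtom
    acceptor: RestraintAtom
    bound: float  # Angstrom
    bound_kind: str  # "upper" | "lower"

    def __post_init__(self):
        if self.bound <= 0:
            raise RestraintError(f"non-positive bound {self.bound}")
        if self.bound_kind not in ("upper", "lower"):
            raise RestraintError(f"bound_kind must be upper|lower, got {self.bound_kind!r}")
        if self.donor.residue_number == self.acceptor.residue_number:
            raise RestraintError(
                f"donor and acceptor share residue {self.donor.residue_number}"
            )


# ---------------------------------------------------------------------------
# coordinate reading


def _convert_gemmi_model(gm: gemmi.Model, model_id: int, polymer_only: bool = True) -> Model:
    """Convert one gemmi model, resolving altlocs to highest occupancy."""
    atoms: list[Atom] = []
    for chain in gm:
        for residue in chain:
            if polymer_only and residue.het_flag != "A":
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                elif atom.occ > prev.occ:  # tie keeps first encountered
                    logger.debug(
                        "altloc %s of %s/%d/%s wins on occupancy %.2f",
                        atom.altloc, chain.name, residue.seqid.num, atom.name, atom.occ,
                    )
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    return Model(model_id=model_id, atoms=atoms)


def _harmonize(models: list[Model]) -> list[Model]:
    """Restrict all models to the intersection of their atom keys, warning on loss."""
    key_sets = [set(a.key() for a in m.atoms) for m in models]
    common = set.intersection(*key_sets)
    if any(ks != common for ks in key_sets):
        lost = max(len(ks) - len(common) for ks in key_sets)
        logger.warning(
            "models differ in atom content; harmonized to %d common atoms "
            "(up to %d atoms dropped per model)", len(common), lost,
        )
        models = [
            Model(m.model_id, [a for a in m.atoms if a.key() in common]) for m in models
        ]
    return models


def read_structure(path: str | Path, format: str | None = None) -> Ensemble:
    """Read a PDB or mmCIF file into an Ensemble, one Model per coordinate model.

    Only polymer (ATOM-record) atoms are kept; alternate locations resolve to
    the highest-occupancy conformer (ties keep the first encountered); models
    with differing atom sets are harmonized to their common skeleton.
    """
    path = Path(path)
    fmt = {
        None: gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    models = [
        _convert_gemmi_model(gm, model_id=i + 1) for i, gm in enumerate(st)
    ]
    models = [m for m in models if m.atoms]
    if not models:
        raise StructureParseError(f"{path}: no polymer models found")
    return Ensemble(models=_harmonize(models), source_ids=[str(path)] * len(models))


def harvest_monomers(
    chain_specs: Sequence[tuple[str | Path, str]],
    offsets: Mapping[str | Path, int] | int = 0,
) -> Ensemble:
    """Collect one Model per (file, chain) pair, renumbered onto a common frame.

    ``chain_specs`` lists (path, chain_id); requesting the same pair twice is
    an error. ``offsets`` maps each path to the integer added to its residue
    numbers (or a single offset for all files; default 0).
    """
    if len(set((str(p), c) for p, c in chain_specs)) != len(chain_specs):
        raise ValueError("duplicate (file, chain) requested in harvest_monomers")
    models: list[Model] = []
    sources: list[str] = []
    for i, (path, chain_id) in enumerate(chain_specs):
        ens = read_structure(path)
        first = ens.models[0]
        available = sorted({a.chain_id for a in first.atoms})
        if chain_id not in available:
            raise ValueError(
                f"chain {chain_id!r} not in {path} (available: {available})"
            )
        if isinstance(offsets, int):
            offset = offsets
        else:
            offset = offsets.get(path, offsets.get(str(path), 0))
        atoms = [
            Atom(
                name=a.name,
                element=a.element,
                residue_number=a.residue_number + offset,
                residue_name=a.residue_name,
                chain_id="A",  # common frame: one chain per monomer model
                xyz=a.xyz,
            )
            for a in first.atoms
            if a.chain_id == chain_id
        ]
        models.append(Model(model_id=i + 1, atoms=atoms))
        sources.append(f"{path}:{chain_id}")
    return Ensemble(models=models, source_ids=sources)


def fetch_structure(pdb_id: str, dest_dir: str | Path) -> Path:
    """Download an mmCIF entry from RCSB into ``dest_dir`` (cached if present).

    Requires network access; deposited reference coordinates are not shipped
    with the package.
    """
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    out = dest_dir / f"{pdb_id.lower()}.cif"
    if out.exists():
        return out
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.cif"
    logger.info("fetching %s", url)
    with urllib.request.urlopen(url, timeout=60) as resp:
        out.write_bytes(resp.read())
    return out


# ---------------------------------------------------------------------------
# shift tables

SHIFT_COLUMNS = ["residue_number", "residue_type", "dH_ppm", "dN_ppm"]


def read_shift_table(path: str | Path) -> ShiftTable:
    """Read a TSV shift table (residue_number, residue_type, dH_ppm, dN_ppm
    [, temperature_K]); prolines may have blank shifts."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"residue_type": str})
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ShiftTableError(f"{path}: missing columns {missing}")
    for col in ("dH_ppm", "dN_ppm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(df.index[bad][0])
            raise ShiftTableError(f"{path}: non-numeric {col} at row {row}")
        df[col] = coerced
    df["residue_number"] = df["residue_number"].astype(int)
    temperature = None
    if "temperature_K" in df.columns:
        temps = df["temperature_K"].dropna().unique()
        if len(temps) > 1:
            raise ShiftTableError(f"{path}: multiple temperatures in one table")
        temperature = float(temps[0]) if len(temps) else None
        df = df.drop(columns=["temperature_K"])
    return ShiftTable(condition_label=path.stem, data=df.reset_index(drop=True),
                      temperature=temperature)


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    """Write a ShiftTable as TSV (shifts at 3 decimals, lossless round trip)."""
    df = table.data.copy()
    if table.temperature is not None:
        df["temperature_K"] = table.temperature
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# CYANA restraints
#
# Fixed-column dialect, one restraint per line:
#   residue_number(>3d) residue_name(<4s) atom_name(<4s) x2, bound(%8.2f)
# e.g. " 125 ARG  H    121 VAL  O       2.00"

_CYANA_FMT = "{:>4d} {:<4s} {:<4s} {:>4d} {:<4s} {:<4s} {:>8.2f}\n"


def write_cyana_restraints(
    restraints: Iterable[DistanceRestraint],
    upper_path: str | Path,
    lower_path: str | Path,
) -> tuple[int, int]:
    """Write upper bounds to ``upper_path`` (.upl) and lower bounds to
    ``lower_path`` (.lol); returns the (upper, lower) line counts."""
    restraints = list(restraints)
    by_pair: dict[tuple, dict[str, float]] = {}
    for r in restraints:
        pair = (r.donor, r.acceptor)
        by_pair.setdefault(pair, {})[r.bound_kind] = r.bound
    for (donor, acceptor), bounds in by_pair.items():
        if "upper" in bounds and "lower" in bounds and bounds["lower"] > bounds["upper"]:
            raise RestraintError(
                f"lower bound {bounds['lower']} exceeds upper {bounds['upper']} for "
                f"{donor.residue_number}{donor.atom_name}-"
                f"{acceptor.residue_number}{acceptor.atom_name}"
            )
    counts = []
    for kind, path in (("upper", upper_path), ("lower", lower_path)):
        lines = [
            _CYANA_FMT.format(
                r.donor.residue_number, r.donor.residue_name, r.donor.atom_name,
                r.acceptor.residue_number, r.acceptor.residue_name, r.acceptor.atom_name,
                r.bound,
            )
            for r in restraints
            if r.bound_kind == kind
        ]
        Path(path).write_text("".join(lines))
        counts.append(len(lines))
    return counts[0], counts[1]


def read_cyana_restraints(path: str | Path, bound_kind: str) -> list[DistanceRestraint]:
    """Parse a CYANA .upl/.lol file written by :func:`write_cyana_restraints`."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise RestraintError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
        out.append(
            DistanceRestraint(
                donor=RestraintAtom(int(parts[0]), parts[1], parts[2]),
                acceptor=RestraintAtom(int(parts[3]), parts[4], parts[5]),
                bound=float(parts[6]),
                bound_kind=bound_kind,
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotated structure writing


def model_to_gemmi(model: Model, bfactors: Mapping[int, float] | None = None) -> gemmi.Structure:
    """Build a gemmi Structure from a Model, optionally setting per-residue B-factors."""
    st = gemmi.Structure()
    gm = gemmi.Model(model.model_id)
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        rkey = (a.chain_id, a.residue_number)
        if rkey not in residues:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "A"
            chains[a.chain_id].add_residue(res)
            residues[rkey] = chains[a.chain_id][-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.xyz)
        atom.occ = 1.0
        b = 0.0
        if bfactors is not None:
            b = float(bfactors.get(a.residue_number, 0.0))
        atom.b_iso = b
        residues[rkey].add_atom(atom)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_annotated_structure(
    model: Model, per_residue_values: Mapping[int, float], path: str | Path
) -> None:
    """Write a PDB with per-residue values in the B-factor column (0.00 where
    absent) so any viewer can color by the annotation."""
    for resnum, value in per_residue_values.items():
        if not math.isfinite(value):
            raise ValueError(f"non-finite annotation value for residue {resnum}")
    present = set(model.residue_numbers())
    for resnum in per_residue_values:
        if resnum not in present:
            logger.warning("annotation for residue %d absent from model; skipped", resnum)
    st = model_to_gemmi(model, bfactors=per_residue_values)
    st.write_pdb(str(path))


def write_ensemble_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL blocks) from an Ensemble."""
    st = gemmi.Structure()
    for m in ensemble.models:
        single = model_to_gemmi(m)
        gm = single[0].clone()
        gm.num = m.model_id
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
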