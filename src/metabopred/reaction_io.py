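"""Parsing, validation, filtering and splitting of atom-mapped metabolic reaction records.

A record is one observed biotransformation: a mapped substrate and one or more
mapped metabolites. Atom-map indices tie each surviving substrate atom to its
image in the product(s); leaving-group atoms are unmapped (or mapped only on
the substrate side), and atoms gained from the medium (e.g. the oxygen of a
hydroxylation) appear unmapped on the product side.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Elements that never count as "metal chelating" contamination. Everything
#: outside this set rejects a record unless the caller overrides the metal set.
NONMETALS = frozenset({"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"})


class RejectReason(str, enum.Enum):
    unparsable = "unparsable"
    r_group = "r_group"
    radical = "radical"
    metal = "metal"
    map_inconsistent = "map_inconsistent"
    no_change = "no_change"
    chirality_only = "chirality_only"


@dataclass
class ReactionRecord:
    """One atom-mapped substrate -> metabolite(s) observation."""

    record_id: str
    substrate_smiles: str
    product_smiles: list[str]
    source: str = "file"  # "file" | "synthetic"
    filter_status: str = "kept"  # "kept" | "rejected"
    reject_reason: Optional[RejectReason] = None
    _substrate_mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)
    _product_mols: Optional[list[Chem.Mol]] = field(default=None, repr=False, compare=False)

    @property
    def substrate_mol(self) -> Optional[Chem.Mol]:
        if self._substrate_mol is None and self.reject_reason != RejectReason.unparsable:
            self._substrate_mol = Chem.MolFromSmiles(self.substrate_smiles)
        return self._substrate_mol

    @property
    def product_mols(self) -> Optional[list[Chem.Mol]]:
        if self._product_mols is None and self.reject_reason != RejectReason.unparsable:
            mols = [Chem.MolFromSmiles(s) for s in self.product_smiles]
            if any(m is None for m in mols):
                return None
            self._product_mols = mols
        return self._product_mols

    def to_reaction_smiles(self) -> str:
        return f"{self.substrate_smiles}>>{'.'.join(self.product_smiles)}"


@dataclass
class DatasetSplit:
    train: list[str]
    validation: list[str]
    test: list[str]
    ratios: tuple[float, float, float]
    seed: int


def _rejected(record_id: str, raw: str, source: str) -> ReactionRecord:
    return ReactionRecord(
        record_id=record_id,
        substrate_smiles=raw,
        product_smiles=[],
        source=source,
        filter_status="rejected",
        reject_reason=RejectReason.unparsable,
    )


def record_from_reaction_smiles(rxn_smiles: str, record_id: str, source: str = "file") -> ReactionRecord:
    """Build a record from ``substrate>>product(.product)*`` reaction SMILES."""
    parts = rxn_smiles.split(">>")
    if len(parts) != 2 or ">" in parts[0] or ">" in parts[1] or not parts[1]:
        return _rejected(record_id, rxn_smiles, source)
    sub = Chem.MolFromSmiles(parts[0])
    prods = [Chem.MolFromSmiles(p) for p in parts[1].split(".")]
    if sub is None or not prods or any(p is None for p in prods):
        return _rejected(record_id, rxn_smiles, source)
    rec = ReactionRecord(
        record_id=record_id,
        substrate_smiles=Chem.MolToSmiles(sub),
        product_smiles=[Chem.MolToSmiles(p) for p in prods],
        source=source,
    )
    rec._substrate_mol = sub
    rec._product_mols = prods
    return rec


def parse_reaction_smiles(path: str | Path) -> list[ReactionRecord]:
    """Read a UTF-8 file of ``reaction_smiles[TAB]record_id`` lines.

    Lines starting with ``#`` and blank lines are skipped. Unparsable lines
    become rejected records (reason ``unparsable``); a missing record id is
    auto-generated from the line position.
    """
    path = Path(path)
    records: list[ReactionRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            rxn = fields[0].strip()
            rid = fields[1].strip() if len(fields) > 1 and fields[1].strip() else f"line{lineno}"
            records.append(record_from_reaction_smiles(rxn, rid))
    return records


def write_reaction_smiles(records: Iterable[ReactionRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.to_reaction_smiles()}\t{rec.record_id}\n")


# ---------------------------------------------------------------------------
# MDL RD-file support
# ---------------------------------------------------------------------------

def parse_rdfile(path: str | Path) -> list[ReactionRecord]:
    """Parse an MDL RD-file ($RDFILE / $RXN / MOL dialect) into records.

    Atom-atom maps are taken from the atom-block mapping field of each MOL
    record. A malformed $RXN block yields a rejected (unparsable) record and
    parsing continues with the next block.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    # locate $RXN block starts
    starts = [i for i, ln in enumerate(lines) if ln.startswith("$RXN")]
    records: list[ReactionRecord] = []
    for n, start in enumerate(starts):
        end = starts[n + 1] if n + 1 < len(starts) else len(lines)
        block = lines[start:end]
        rid = f"rxn{n + 1}"
        rec = _parse_rxn_block(block, rid)
        records.append(rec)
    return records


def _parse_rxn_block(block: list[str], rid: str) -> ReactionRecord:
    try:
        # $RXN, name, program, comment, counts
        counts = block[4].split()
        n_react, n_prod = int(counts[0]), int(counts[1])
        if n_react != 1 or n_prod < 1:
            return _rejected(rid, "$RXN", "file")
        mol_starts = [i for i, ln in enumerate(block) if ln.startswith("$MOL")]
        if len(mol_starts) < n_react + n_prod:
            return _rejected(rid, "$RXN", "file")
        mols: list[Chem.Mol] = []
        for k in range(n_react + n_prod):
            mstart = mol_starts[k] + 1
            mend = mol_starts[k + 1] if k + 1 < len(mol_starts) else len(block)
            molblock_lines = block[mstart:mend]
            # trim trailing non-mol lines ($DTYPE etc.)
            for j, ln in enumerate(molblock_lines):
                if ln.startswith("M  END"):
                    molblock_lines = molblock_lines[: j + 1]
                    break
            else:
                return _rejected(rid, "$RXN", "file")
            mol = Chem.MolFromMolBlock("\n".join(molblock_lines))
            if mol is None:
                return _rejected(rid, "$RXN", "file")
            mols.append(mol)
        sub, prods = mols[0], mols[1:]
        rec = ReactionRecord(
            record_id=rid,
            substrate_smiles=Chem.MolToSmiles(sub),
            product_smiles=[Chem.MolToSmiles(p) for p in prods],
            source="file",
        )
        rec._substrate_mol = sub
        rec._product_mols = prods
        return rec
    except (IndexError, ValueError):
        return _rejected(rid, "$RXN", "file")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _canonical(mol: Chem.Mol, strip_stereo: bool) -> str:
    m = Chem.Mol(mol)
    for a in m.GetAtoms():
        a.SetAtomMapNum(0)
    if strip_stereo:
        Chem.RemoveStereochemistry(m)
    return Chem.MolToSmiles(m)


def _map_numbers(mol: Chem.Mol) -> list[int]:
    return [a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0]


def _classify(record: ReactionRecord, metal_symbols: frozenset[str]) -> Optional[RejectReason]:
    """Return the first matching reject reason, or None for a kept record.

    Priority: unparsable -> r_group -> radical -> metal -> map_inconsistent
    -> no_change -> chirality_only.
    """
    if record.reject_reason == RejectReason.unparsable:
        return RejectReason.unparsable
    sub = record.substrate_mol
    prods = record.product_mols
    if sub is None or prods is None or not prods:
        return RejectReason.unparsable

    mols = [sub] + prods
    if any(a.GetAtomicNum() == 0 for m in mols for a in m.GetAtoms()):
        return RejectReason.r_group
    if any(a.GetNumRadicalElectrons() > 0 for m in mols for a in m.GetAtoms()):
        return RejectReason.radical
    if any(a.GetSymbol() in metal_symbols for m in mols for a in m.GetAtoms()):
        return RejectReason.metal

    sub_maps = _map_numbers(sub)
    if len(sub_maps) != len(set(sub_maps)):
        return RejectReason.map_inconsistent
    sub_map_set = set(sub_maps)
    prod_maps: list[int] = []
    for p in prods:
        pm = _map_numbers(p)
        if not pm:
            return RejectReason.map_inconsistent  # wholly unmapped product
        prod_maps.extend(pm)
        # gained heavy atoms must be anchored to a mapped atom so the
        # template extractor can attribute them
        for a in p.GetAtoms():
            if a.GetAtomMapNum() == 0 and a.GetAtomicNum() > 1:
                if not any(nb.GetAtomMapNum() > 0 for nb in a.GetNeighbors()):
                    return RejectReason.map_inconsistent
    if len(prod_maps) != len(set(prod_maps)):
        return RejectReason.map_inconsistent
    if not set(prod_maps) <= sub_map_set:
        return RejectReason.map_inconsistent

    sub_exact = _canonical(sub, strip_stereo=False)
    sub_flat = _canonical(sub, strip_stereo=True)
    if all(_canonical(p, strip_stereo=False) == sub_exact for p in prods):
        return RejectReason.no_change
    if all(_canonical(p, strip_stereo=True) == sub_flat for p in prods):
        return RejectReason.chirality_only
    return None


def filter_records(
    records: Sequence[ReactionRecord],
    metal_symbols: Optional[Iterable[str]] = None,
) -> tuple[list[ReactionRecord], list[ReactionRecord]]:
    """Assign filter status to every record; return (kept, rejected).

    ``metal_symbols`` defaults to every element outside the nonmetal set.
    Filtering is total and idempotent.
    """
    if metal_symbols is None:
        metals = frozenset(
            Chem.GetPeriodicTable().GetElementSymbol(z) for z in range(1, 119)
        ) - NONMETALS
    else:
        metals = frozenset(metal_symbols)
    kept, rejected = [], []
    for rec in records:
        reason = _classify(rec, metals)
        if reason is None:
            rec.filter_status = "kept"
            rec.reject_reason = None
            kept.append(rec)
        else:
            rec.filter_status = "rejected"
            rec.reject_reason = reason
            rejected.append(rec)
    return kept, rejected


def write_filter_report(records: Iterable[ReactionRecord], path: str | Path) -> None:
    """TSV report: record_id, status, reason."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("record_id\tstatus\treason\n")
        for rec in records:
            reason = rec.reject_reason.value if rec.reject_reason else ""
            fh.write(f"{rec.record_id}\t{rec.filter_status}\t{reason}\n")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _partition_sizes(n: int, ratios: Sequence[float]) -> list[int]:
    # floor + largest-remainder so realized sizes are within 1 of n * ratio
    raw = [n * r for r in ratios]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = np.argsort([-(x - int(np.floor(x))) for x in raw], kind="stable")
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def split_dataset(
    records: Sequence[ReactionRecord],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Shuffle kept records with a seeded PRNG and slice into train/val/test."""
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive fractions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    ids = [r.record_id for r in records]
    if len(ids) < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    n_train, n_val, n_test = _partition_sizes(len(ids), ratios)
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        ratios=tuple(ratios),
        seed=seed,
    )
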