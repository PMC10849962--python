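"""Reading, writing, filtering and labelling SURF reaction tables.

SURF (simple user-friendly reaction format) is a flat, tab-separated,
one-row-per-reaction text format for capturing reaction conditions and
outcomes.  The dialect implemented here uses the columns

    rxn_id, source, startingmat_1_smiles, product_1_smiles ... product_k_smiles,
    catalyst, ligand, solvent, reagent, temperature_deg_c, time_h,
    concentration_mol_l, scale_mol, yield_1_percent, binary_outcome, provenance

with UTF-8 encoding and csv-style quoting so embedded tabs, quotes and
newlines round-trip.  Unknown columns are preserved verbatim in an extras
map.  Missing numeric cells (empty, "n.d.", "na", "nan") become None,
never zero.

The module also derives the three training labels used downstream:
binary reaction outcome at a conversion threshold, reaction yield, and
per-atom regioselectivity labels obtained by mapping pinacol-boronate
(Bpin) substituted products back onto their substrates.
"""

from __future__ import annotations

import csv
import io
import re
from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ReactionRecord",
    "RegioLabel",
    "SurfDialect",
    "SurfFormatError",
    "LabelingError",
    "read_surf",
    "write_surf",
    "validate_surf",
    "binarize_outcome",
    "filter_yield_dataset",
    "filter_regio_dataset",
    "extract_regio_labels",
    "substrate_mol",
]

MISSING_TOKENS = {"", "n.d.", "nd", "na", "n/a", "nan", "none", "missing"}

#: Accepted spellings of the bis(pinacolato)diboron reagent.
B2PIN2_NAMES = {"b2pin2", "bis(pinacolato)diboron", "b2(pin)2"}

_BPIN_SMARTS = Chem.MolFromSmarts("B1OC(C)(C)C(C)(C)O1")


class SurfFormatError(ValueError):
    """Raised when a SURF file violates the dialect (e.g. missing column)."""


class LabelingError(ValueError):
    """Raised when a product cannot be mapped back onto its substrate."""


@dataclass
class SurfDialect:
    delimiter: str = "\t"
    required: tuple[str, ...] = (
        "rxn_id",
        "source",
        "startingmat_1_smiles",
        "catalyst",
        "ligand",
        "solvent",
        "reagent",
        "temperature_deg_c",
        "time_h",
        "concentration_mol_l",
        "scale_mol",
        "yield_1_percent",
        "provenance",
    )
    product_prefix: str = "product_"
    product_suffix: str = "_smiles"
    outcome_column: str = "binary_outcome"


DEFAULT_DIALECT = SurfDialect()


@dataclass
class ReactionRecord:
    """One SURF row: a single reaction with conditions and outcome."""

    rxn_id: str
    source: str  # "literature" or "experimental"
    substrate: str  # SMILES
    products: list[str] = field(default_factory=list)
    catalyst: str = ""
    ligand: str = ""
    solvent: str = ""
    reagent: str = ""
    temperature: float | None = None  # deg C
    time: float | None = None  # h
    concentration: float | None = None  # mol/L
    scale: float | None = None  # mmol
    yield_percent: float | None = None
    outcome: bool | None = None
    citation: str = ""
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.yield_percent is not None and not 0.0 <= self.yield_percent <= 100.0:
            raise ValueError(
                f"yield_percent out of [0, 100] for {self.rxn_id}: {self.yield_percent}"
            )


@dataclass(frozen=True)
class RegioLabel:
    """Per-atom regioselectivity label on the substrate's canonical order."""

    atom_index: int
    is_candidate: bool  # carbon bearing >= 1 hydrogen (non-quaternary C)
    is_reactive: bool  # carries Bpin in any product

    def __post_init__(self):
        if self.is_reactive and not self.is_candidate:
            raise ValueError("reactive atom must be a candidate (H-bearing carbon)")


# --------------------------------------------------------------------- parse


def _parse_float(cell: str) -> float | None:
    if cell is None or cell.strip().lower() in MISSING_TOKENS:
        return None
    return float(cell)


def _parse_bool(cell: str) -> bool | None:
    c = (cell or "").strip().lower()
    if c in MISSING_TOKENS:
        return None
    if c in {"1", "true", "yes", "y"}:
        return True
    if c in {"0", "false", "no", "n"}:
        return False
    raise ValueError(f"unparseable boolean cell: {cell!r}")


def _format_float(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))


def read_surf(
    path,
    dialect: SurfDialect = DEFAULT_DIALECT,
    errors: list[dict] | None = None,
) -> list[ReactionRecord]:
    """Read a SURF table into reaction records.

    Row-level problems (malformed SMILES, bad numerics, out-of-range yields)
    are collected into `errors` (a list of dicts naming the row and problem)
    when provided; the offending rows are skipped.  Without an `errors`
    collector, row-level problems raise.  A header missing a required column
    always raises :class:`SurfFormatError`.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _read_surf_stream(fh, dialect, errors)


def _read_surf_stream(fh, dialect, errors):
    reader = csv.reader(fh, delimiter=dialect.delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise SurfFormatError("empty SURF file: no header row") from None
    missing = [c for c in dialect.required if c not in header]
    if missing:
        raise SurfFormatError(f"SURF header is missing required column(s): {missing}")

    prod_re = re.compile(
        re.escape(dialect.product_prefix) + r"(\d+)" + re.escape(dialect.product_suffix) + r"$"
    )
    prod_cols = sorted(
        ((int(m.group(1)), c) for c in header if (m := prod_re.match(c))),
    )
    known = set(dialect.required) | {c for _, c in prod_cols} | {dialect.outcome_column}
    col = {c: i for i, c in enumerate(header)}

    records: list[ReactionRecord] = []
    seen_ids: set[str] = set()
    for row_no, row in enumerate(reader, start=2):
        if not row or all(c == "" for c in row):
            continue
        row = list(row) + [""] * (len(header) - len(row))

        def cell(name: str) -> str:
            return row[col[name]]

        try:
            substrate = cell("startingmat_1_smiles")
            if Chem.MolFromSmiles(substrate) is None:
                raise ValueError(f"malformed substrate SMILES: {substrate!r}")
            products = []
            for _, c in prod_cols:
                p = cell(c).strip()
                if p:
                    if Chem.MolFromSmiles(p) is None:
                        raise ValueError(f"malformed product SMILES: {p!r}")
                    products.append(p)
            outcome = None
            if dialect.outcome_column in col:
                outcome = _parse_bool(cell(dialect.outcome_column))
            rec = ReactionRecord(
                rxn_id=cell("rxn_id"),
                source=cell("source"),
                substrate=substrate,
                products=products,
                catalyst=cell("catalyst"),
                ligand=cell("ligand"),
                solvent=cell("solvent"),
                reagent=cell("reagent"),
                temperature=_parse_float(cell("temperature_deg_c")),
                time=_parse_float(cell("time_h")),
                concentration=_parse_float(cell("concentration_mol_l")),
                scale=_parse_float(cell("scale_mol")),
                yield_percent=_parse_float(cell("yield_1_percent")),
                outcome=outcome,
                citation=cell("provenance"),
                extras={c: row[col[c]] for c in header if c not in known},
            )
            if rec.rxn_id in seen_ids:
                raise ValueError(f"duplicate rxn_id: {rec.rxn_id}")
            seen_ids.add(rec.rxn_id)
        except ValueError as exc:
            if errors is None:
                raise
            errors.append({"row": row_no, "rxn_id": cell("rxn_id"), "error": str(exc)})
            continue
        records.append(rec)
    return records


def write_surf(records: list[ReactionRecord], path, dialect: SurfDialect = DEFAULT_DIALECT):
    """Write records as a SURF table; inverse of :func:`read_surf`."""
    n_prod = max((len(r.products) for r in records), default=0)
    prod_cols = [
        f"{dialect.product_prefix}{i + 1}{dialect.product_suffix}" for i in range(n_prod)
    ]
    extra_cols: list[str] = []
    for r in records:
        for c in r.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    header = (
        ["rxn_id", "source", "startingmat_1_smiles"]
        + prod_cols
        + [
            "catalyst",
            "ligand",
            "solvent",
            "reagent",
            "temperature_deg_c",
            "time_h",
            "concentration_mol_l",
            "scale_mol",
            "yield_1_percent",
            dialect.outcome_column,
            "provenance",
        ]
        + extra_cols
    )
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=dialect.delimiter, lineterminator="\n")
    writer.writerow(header)
    for r in records:
        prods = list(r.products) + [""] * (n_prod - len(r.products))
        outcome = "" if r.outcome is None else ("1" if r.outcome else "0")
        writer.writerow(
            [r.rxn_id, r.source, r.substrate]
            + prods
            + [
                r.catalyst,
                r.ligand,
                r.solvent,
                r.reagent,
                _format_float(r.temperature),
                _format_float(r.time),
                _format_float(r.concentration),
                _format_float(r.scale),
                _format_float(r.yield_percent),
                outcome,
                r.citation,
            ]
            + [r.extras.get(c, "") for c in extra_cols]
        )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def validate_surf(path, dialect: SurfDialect = DEFAULT_DIALECT) -> dict:
    """Validate a SURF file; returns a JSON-serializable report."""
    errors: list[dict] = []
    try:
        records = read_surf(path, dialect, errors)
    except SurfFormatError as exc:
        return {"valid": False, "n_records": 0, "format_error": str(exc), "row_errors": []}
    return {
        "valid": not errors,
        "n_records": len(records),
        "format_error": None,
        "row_errors": errors,
    }


# -------------------------------------------------------------------- labels


def binarize_outcome(
    yield_percent: float | None, threshold: float = 1.0, inclusive: bool | None = None
) -> bool | None:
    """Binary reaction outcome from a conversion threshold.

    Success is conversion >= 1% at the default threshold; the stricter
    thresholds 5/10/20% use a strict > comparison.  Missing yields
    propagate as None.
    """
    if threshold not in (1, 5, 10, 20):
        raise ValueError(f"threshold must be one of 1, 5, 10, 20 (%); got {threshold}")
    if inclusive is None:
        inclusive = threshold == 1
    if yield_percent is None:
        return None
    return yield_percent >= threshold if inclusive else yield_percent > threshold


def _dedup(records: list[ReactionRecord], key) -> list[ReactionRecord]:
    """Keep one record per key; among duplicates keep the highest yield."""
    best: dict[tuple, ReactionRecord] = {}
    for r in records:
        k = key(r)
        cur = best.get(k)
        y = -1.0 if r.yield_percent is None else r.yield_percent
        ycur = -1.0 if cur is None or cur.yield_percent is None else cur.yield_percent
        if cur is None or y > ycur:
            best[k] = r
    return sorted(best.values(), key=lambda r: r.rxn_id)


def filter_yield_dataset(records: list[ReactionRecord]) -> list[ReactionRecord]:
    """Literature-set filter for the yield-prediction task.

    Removes duplicate reactions (identical substrate, catalyst, solvent,
    reagent and product set; the highest-yield duplicate is kept), then keeps
    only records whose catalyst, solvent and reagent values each occur at
    least four times in the remaining set.  The occurrence filter is iterated
    to a fixed point so the operation is idempotent.  Output is ordered by
    rxn_id.
    """
    out = _dedup(
        records,
        key=lambda r: (r.substrate, r.catalyst, r.solvent, r.reagent, tuple(sorted(r.products))),
    )
    while True:
        cat = Counter(r.catalyst for r in out)
        sol = Counter(r.solvent for r in out)
        rea = Counter(r.reagent for r in out)
        kept = [
            r for r in out if cat[r.catalyst] >= 4 and sol[r.solvent] >= 4 and rea[r.reagent] >= 4
        ]
        if len(kept) == len(out):
            return out
        out = kept


def _is_b2pin2(reagent: str) -> bool:
    return reagent.strip().lower() in B2PIN2_NAMES


def filter_regio_dataset(records: list[ReactionRecord]) -> list[ReactionRecord]:
    """Literature-set filter for the regioselectivity task.

    Keeps only reactions using B2Pin2 with an annotated yield of at least
    30%, then removes duplicate products (highest-yield duplicate kept).
    Idempotent; output ordered by rxn_id.
    """
    kept = [
        r
        for r in records
        if _is_b2pin2(r.reagent) and r.yield_percent is not None and r.yield_percent >= 30.0
    ]
    return _dedup(kept, key=lambda r: tuple(sorted(r.products)))


# ----------------------------------------------------------- regio labelling


def substrate_mol(smiles: str) -> Chem.Mol:
    """Substrate as an explicit-hydrogen molecule in canonical atom order.

    All atom indices used for regioselectivity labels and molecular graphs
    refer to this ordering (heavy atoms in canonical SMILES order, explicit
    hydrogens appended), so labels and graphs stay aligned.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"malformed SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    return Chem.AddHs(mol)


def _deborylated_cores(product_smiles: str) -> list[tuple[Chem.Mol, int]]:
    """Remove each Bpin group from a product.

    Returns one (core molecule, attachment atom index in core) pair per Bpin
    group; di-borylated products yield a single core with both attachment
    atoms reported.
    """
    pmol = Chem.MolFromSmiles(product_smiles)
    if pmol is None:
        raise ValueError(f"malformed product SMILES: {product_smiles!r}")
    matches = pmol.GetSubstructMatches(_BPIN_SMARTS)
    if not matches:
        raise LabelingError(f"no pinacol-boronate group found in product {product_smiles!r}")
    bpin_atoms = sorted({i for m in matches for i in m}, reverse=True)
    bpin_set = set(bpin_atoms)
    attachments = []
    for m in matches:
        boron = m[0]
        nbrs = [
            n.GetIdx()
            for n in pmol.GetAtomWithIdx(boron).GetNeighbors()
            if n.GetIdx() not in bpin_set
        ]
        if len(nbrs) != 1:
            raise LabelingError(f"ambiguous Bpin attachment in {product_smiles!r}")
        attachments.append(nbrs[0])
    rw = Chem.RWMol(pmol)
    for idx in bpin_atoms:  # descending order keeps smaller indices stable
        rw.RemoveAtom(idx)
    shift = [sum(1 for b in bpin_atoms if b < a) for a in attachments]
    core = rw.GetMol()
    Chem.SanitizeMol(core)
    return [(core, a - s) for a, s in zip(attachments, shift)]


def extract_regio_labels(
    substrate: str, products: list[str], rxn_id: str = "?"
) -> list[RegioLabel]:
    """Per-atom reactive/candidate labels for a substrate.

    Candidate atoms are the non-quaternary carbons (carbons bearing at least
    one hydrogen).  Reactive atoms are the substrate carbons carrying a
    pinacol-boronate group in any product, located by deleting the boronate
    substructure from the product and mapping the remaining core onto the
    substrate.  Indices refer to :func:`substrate_mol` ordering.
    """
    smol = substrate_mol(substrate)
    heavy = Chem.RemoveHs(smol)
    reactive: set[int] = set()
    for prod in products:
        try:
            cores = _deborylated_cores(prod)
        except LabelingError as exc:
            raise LabelingError(f"[{rxn_id}] {exc}") from None
        for core, attach in cores:
            match = heavy.GetSubstructMatch(core)
            if not match or len(match) != core.GetNumAtoms():
                raise LabelingError(
                    f"[{rxn_id}] de-borylated product does not map onto substrate "
                    f"{substrate!r} (product {prod!r})"
                )
            # symmetry-equivalent atoms are interchangeable: canonicalize the
            # mapped site to the lowest index in its automorphism orbit
            ranks = list(Chem.CanonicalRankAtoms(heavy, breakTies=False))
            site = match[attach]
            reactive.add(min(i for i, rk in enumerate(ranks) if rk == ranks[site]))
    labels = []
    for atom in smol.GetAtoms():
        idx = atom.GetIdx()
        is_cand = atom.GetSymbol() == "C" and atom.GetTotalNumHs(includeNeighbors=True) >= 1
        is_react = idx in reactive
        if is_react and not is_cand:
            raise LabelingError(
                f"[{rxn_id}] mapped reactive atom {idx} is not an H-bearing carbon"
            )
        labels.append(RegioLabel(idx, is_cand, is_react))
    return labels
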