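"""Readers, writers and validated domain containers for the pipeline's inputs.

Formats handled here:

* prescription transactions — CSV with header ``prescription_id,cohort,herbs``,
  the ``herbs`` field semicolon-separated;
* gene-set collections — GMT (``term<TAB>description<TAB>gene...``);
* protein interaction edges — 3-column TSV with a confidence score, either
  already in [0, 1] or on the STRING 0–1000 scale (auto-detected);
* disease-gene / seed lists — one ID per line;
* herb annotations — long-form TSV ``herb_id<TAB>relation<TAB>value`` with
  relation in {compound, target, symptom}.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Transaction",
    "TransactionDB",
    "GeneSetCollection",
    "HerbAnnotation",
    "FormatError",
    "ValidationError",
    "read_transactions",
    "write_transactions",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_id_list",
    "write_id_list",
    "read_annotations",
    "write_annotations",
    "read_compound_targets",
    "write_compound_targets",
]

COHORTS = ("case", "control")


class FormatError(ValueError):
    """A file does not have the expected structure (columns, field counts)."""


class ValidationError(ValueError):
    """A file parses but its content violates a domain invariant."""


@dataclass(frozen=True)
class Transaction:
    """One prescription: an ID, a cohort label and the set of herbs it contains."""

    prescription_id: str
    cohort: str
    herbs: frozenset[str]

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"transaction {self.prescription_id!r}: cohort must be one of "
                f"{COHORTS}, got {self.cohort!r}"
            )
        if not self.herbs:
            raise ValidationError(
                f"transaction {self.prescription_id!r}: herb set is empty"
            )


@dataclass(frozen=True)
class TransactionDB:
    """A cohort-labelled prescription database.

    Each transaction is one prescription; herbs are presence-based sets, so a
    herb mentioned twice in one prescription counts once everywhere downstream
    (supports, co-occurrence weights, relative-risk numerators).
    """

    transactions: tuple[Transaction, ...]

    def __post_init__(self) -> None:
        ids = [t.prescription_id for t in self.transactions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i, c in Counter(ids).items() if c > 1})
            raise ValidationError(f"duplicate prescription_ids: {dupes[:10]}")

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self):
        return iter(self.transactions)

    @property
    def herbs(self) -> frozenset[str]:
        """Union of all herbs appearing in any prescription."""
        out: set[str] = set()
        for t in self.transactions:
            out |= t.herbs
        return frozenset(out)

    def cohort_counts(self) -> dict[str, int]:
        c = Counter(t.cohort for t in self.transactions)
        return {k: c.get(k, 0) for k in COHORTS}

    def filter_cohort(self, cohort: str) -> "TransactionDB":
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort {cohort!r}")
        kept = tuple(t for t in self.transactions if t.cohort == cohort)
        return TransactionDB(kept)

    def total_herb_uses(self) -> int:
        """Total herb-use count: one use per (prescription, herb) pair."""
        return sum(len(t.herbs) for t in self.transactions)

    def herb_use_counts(self) -> Counter:
        """Number of prescriptions containing each herb."""
        c: Counter = Counter()
        for t in self.transactions:
            c.update(t.herbs)
        return c


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the gene universe they are tested against.

    Invariant: every member of every set belongs to the universe; sets are
    non-empty.
    """

    sets: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {term!r} is empty")
            stray = genes - self.universe
            if stray:
                raise ValidationError(
                    f"gene set {term!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def genes_of(self, term: str) -> frozenset[str]:
        return self.sets[term][1]


@dataclass(frozen=True)
class HerbAnnotation:
    """Compounds, protein targets and clinical symptoms annotated to one herb."""

    herb_id: str
    compounds: frozenset[str] = field(default_factory=frozenset)
    targets: frozenset[str] = field(default_factory=frozenset)
    symptoms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        pools = [self.compounds, self.targets, self.symptoms]
        for i in range(3):
            for j in range(i + 1, 3):
                clash = pools[i] & pools[j]
                if clash:
                    raise ValidationError(
                        f"herb {self.herb_id!r}: ID namespaces overlap: "
                        f"{sorted(clash)[:5]}"
                    )


# ---------------------------------------------------------------------------
# transactions CSV
# ---------------------------------------------------------------------------

def read_transactions(
    path: str | Path,
    cohort_map: Mapping[str, str] | None = None,
) -> TransactionDB:
    """Read a prescription CSV into a :class:`TransactionDB`.

    Parameters
    ----------
    path:
        CSV file with header ``prescription_id,cohort,herbs``; the herbs field
        is semicolon-separated. Duplicate herb mentions within one prescription
        collapse to one (set semantics).
    cohort_map:
        Optional dialect mapping from raw cohort labels to ``case``/``control``
        (e.g. ``{"HN": "case"}``). Labels already equal to a canonical cohort
        pass through.
    """
    path = Path(path)
    cohort_map = dict(cohort_map or {})
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        for required in ("prescription_id", "cohort", "herbs"):
            if required not in cols:
                raise FormatError(f"{path}: missing required column {required!r}")
        rows = list(reader)

    bad_rows: list[str] = []
    transactions: list[Transaction] = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        raw = row["cohort"].strip()
        cohort = cohort_map.get(raw, raw)
        if cohort not in COHORTS:
            bad_rows.append(f"line {i}: {raw!r}")
            continue
        herbs = frozenset(h.strip() for h in row["herbs"].split(";") if h.strip())
        transactions.append(Transaction(row["prescription_id"].strip(), cohort, herbs))
    if bad_rows:
        raise ValidationError(
            f"{path}: unknown cohort labels (expected {COHORTS} or mapped): "
            + "; ".join(bad_rows[:10])
        )
    return TransactionDB(tuple(transactions))


def write_transactions(db: TransactionDB, path: str | Path) -> None:
    """Write a :class:`TransactionDB` in the canonical CSV layout."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["prescription_id", "cohort", "herbs"])
        for t in db.transactions:
            w.writerow([t.prescription_id, t.cohort, ";".join(sorted(t.herbs))])


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file. The universe defaults to the union of all member genes."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            term, desc, *genes = fields
            if term in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate term {term!r}")
            gene_set = frozenset(g for g in genes if g)
            if not gene_set:
                raise ValidationError(f"{path}: line {lineno}: term {term!r} has no genes")
            sets[term] = (desc, gene_set)
    if universe is None:
        uni: frozenset[str] = frozenset().union(*(g for _, g in sets.values())) if sets else frozenset()
    else:
        uni = frozenset(universe)
    return GeneSetCollection(sets, uni)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in canonical GMT form (terms and genes sorted)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for term in sorted(collection.sets):
            desc, genes = collection.sets[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# interaction edge lists
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    min_confidence: float = 0.0,
) -> dict[tuple[str, str], float]:
    """Read a 3-column interaction TSV and filter by confidence.

    Scores may be on [0, 1] or STRING-style [0, 1000]; any score > 1 anywhere
    in the file switches the whole file to the 0–1000 scale (divided by 1000).
    Self-loops are dropped; duplicate undirected pairs keep the maximum
    confidence; only edges with confidence >= ``min_confidence`` are returned,
    keyed by the sorted node pair.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must lie in [0, 1]")
    path = Path(path)
    raw: list[tuple[str, str, float]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields"
                )
            a, b, score_s = fields[0], fields[1], fields[2]
            if lineno == 1 and not _is_number(score_s):
                continue  # header row
            score = float(score_s)
            if score < 0 or score > 1000:
                raise ValidationError(
                    f"{path}: line {lineno}: score {score} outside [0, 1000]"
                )
            raw.append((a, b, score))
    string_scale = any(s > 1.0 for _, _, s in raw)
    edges: dict[tuple[str, str], float] = {}
    for a, b, score in raw:
        if a == b:
            continue
        conf = score / 1000.0 if string_scale else score
        key = (a, b) if a <= b else (b, a)
        if conf > edges.get(key, -1.0):
            edges[key] = conf
    return {k: v for k, v in edges.items() if v >= min_confidence}


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def write_edge_list(edges: Mapping[tuple[str, str], float], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for (a, b), conf in sorted(edges.items()):
            fh.write(f"{a}\t{b}\t{conf:.6g}\n")


# ---------------------------------------------------------------------------
# plain ID lists and herb annotations
# ---------------------------------------------------------------------------

def read_id_list(path: str | Path) -> list[str]:
    """One ID per line; blank lines and '#' comments skipped; order preserved."""
    out: list[str] = []
    seen: set[str] = set()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            tok = line.strip()
            if not tok or tok.startswith("#"):
                continue
            if tok not in seen:
                seen.add(tok)
                out.append(tok)
    return out


def write_id_list(ids: Sequence[str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for tok in ids:
            fh.write(f"{tok}\n")


def read_compound_targets(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a 2-column compound→target TSV (optional header) into a map."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 fields")
            c, t = (f.strip() for f in fields)
            if lineno == 1 and (c.lower(), t.lower()) == ("compound", "target"):
                continue
            out.setdefault(c, set()).add(t)
    return {c: frozenset(ts) for c, ts in out.items()}


def write_compound_targets(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("compound\ttarget\n")
        for c in sorted(mapping):
            for t in sorted(mapping[c]):
                fh.write(f"{c}\t{t}\n")


_RELATIONS = ("compound", "target", "symptom")


def read_annotations(path: str | Path) -> list[HerbAnnotation]:
    """Read long-form herb annotations (herb_id, relation, value) into records."""
    path = Path(path)
    buckets: dict[str, dict[str, set[str]]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 fields")
            herb, rel, value = (f.strip() for f in fields)
            if lineno == 1 and rel not in _RELATIONS:
                continue  # header row
            if rel not in _RELATIONS:
                raise ValidationError(
                    f"{path}: line {lineno}: relation {rel!r} not in {_RELATIONS}"
                )
            buckets.setdefault(herb, {r: set() for r in _RELATIONS})[rel].add(value)
    return [
        HerbAnnotation(
            herb_id=h,
            compounds=frozenset(d["compound"]),
            targets=frozenset(d["target"]),
            symptoms=frozenset(d["symptom"]),
        )
        for h, d in sorted(buckets.items())
    ]


def write_annotations(annotations: Sequence[HerbAnnotation], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("herb_id\trelation\tvalue\n")
        for ann in annotations:
            for rel, values in (
                ("compound", ann.compounds),
                ("target", ann.targets),
                ("symptom", ann.symptoms),
            ):
                for v in sorted(values):
                    fh.write(f"{ann.herb_id}\t{rel}\t{v}\n")
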