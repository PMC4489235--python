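"""Compound-name standardization and identifier conversion.

Queries are resolved against a :class:`CompoundLibrary` through a cascade:
exact primary-name match, synonym match, direct ID match (HMDB / KEGG /
PubChem patterns auto-detected), then heuristically pruned fuzzy matching by
normalized edit-distance similarity.  The pruning (length window plus shared
token or 3-gram) is a speedup only: it returns the same best match as an
exhaustive scan of the library.

The bundled library (``data/compound_library_synthetic.tsv``) is a small
synthetic stand-in for a real reference compound database: common metabolite
names and synonyms paired with identifiers that follow the HMDB/KEGG/PubChem
formats but are not authoritative.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

try:
    import edlib
    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

#: Fuzzy acceptance: similarity threshold and required margin over runner-up.
FUZZY_THRESHOLD = 0.85
FUZZY_MARGIN = 0.02
#: Candidate pruning: length window as a fraction of the query length.
LENGTH_WINDOW = 0.30
N_CANDIDATES = 5

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})

_HMDB_RE = re.compile(r"^HMDB\d+$", re.IGNORECASE)
_KEGG_RE = re.compile(r"^C\d{5}$", re.IGNORECASE)
_PUBCHEM_RE = re.compile(r"^\d+$")

NAMESPACES = ("hmdb", "kegg", "pubchem", "name")


def normalize_name(name: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return " ".join(str(name).lower().translate(_PUNCT_TABLE).split())


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (edlib-backed, pure-Python fallback)."""
    if _HAVE_EDLIB:
        return edlib.align(a, b)["editDistance"]
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def similarity(a: str, b: str) -> float:
    """1 − edit distance / max length, in [0, 1]."""
    if not a and not b:
        return 1.0
    return 1.0 - edit_distance(a, b) / max(len(a), len(b))


@dataclass
class CompoundRecord:
    primary_name: str
    synonyms: list
    hmdb_id: str | None = None
    kegg_id: str | None = None
    pubchem_id: str | None = None


@dataclass
class CompoundLibrary:
    records: list

    def __post_init__(self) -> None:
        self.by_name: dict[str, CompoundRecord] = {}
        self.by_synonym: dict[str, CompoundRecord] = {}
        self.by_id: dict[str, CompoundRecord] = {}
        for rec in self.records:
            key = normalize_name(rec.primary_name)
            if key in self.by_name:
                raise ValueError(f"duplicate primary name {rec.primary_name!r}")
            self.by_name[key] = rec
            for syn in rec.synonyms:
                self.by_synonym.setdefault(normalize_name(syn), rec)
            for cid in (rec.hmdb_id, rec.kegg_id, rec.pubchem_id):
                if cid:
                    cid_up = cid.upper()
                    if cid_up in self.by_id:
                        raise ValueError(f"id {cid} indexed twice")
                    self.by_id[cid_up] = rec

    def __len__(self) -> int:
        return len(self.records)

    #: every searchable (normalized name, record) pair
    def _name_pool(self):
        pool = [(k, r) for k, r in self.by_name.items()]
        pool += [(k, r) for k, r in self.by_synonym.items()]
        return pool


def load_library(path=None) -> CompoundLibrary:
    """Load a TSV compound library (columns: name, synonyms, hmdb, kegg,
    pubchem; synonyms semicolon-joined).  With no path, loads the bundled
    synthetic library."""
    if path is None:
        ref = resources.files("metabokit").joinpath(
            "data/compound_library_synthetic.tsv")
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in frame.iterrows():
        syns = [s.strip() for s in row.get("synonyms", "").split(";") if s.strip()]
        records.append(CompoundRecord(
            primary_name=row["name"], synonyms=syns,
            hmdb_id=row.get("hmdb") or None,
            kegg_id=row.get("kegg") or None,
            pubchem_id=row.get("pubchem") or None))
    return CompoundLibrary(records)


@dataclass
class MappingResult:
    query: str
    status: str                      # exact | synonym | fuzzy | unmatched
    matched_record: CompoundRecord | None = None
    match_score: float = 0.0
    candidates: list = field(default_factory=list)   # (name, score) ranked


def _tokens(name: str) -> set:
    return set(name.split())


def _trigrams(name: str) -> set:
    s = name.replace(" ", "")
    return {s[i:i + 3] for i in range(len(s) - 2)} if len(s) >= 3 else {s}


def _fuzzy_candidates(qnorm: str, lib: CompoundLibrary, prune: bool = True):
    """Rank library names by similarity; optionally prune to names within
    ±30% length sharing a token or 3-gram with the query."""
    qtok, qtri = _tokens(qnorm), _trigrams(qnorm)
    lo = len(qnorm) * (1 - LENGTH_WINDOW)
    hi = len(qnorm) * (1 + LENGTH_WINDOW)
    scored = {}
    for name, rec in lib._name_pool():
        if prune:
            if not lo <= len(name) <= hi:
                continue
            if not (_tokens(name) & qtok) and not (_trigrams(name) & qtri):
                continue
        s = similarity(qnorm, name)
        key = id(rec)
        if key not in scored or s > scored[key][1]:
            scored[key] = (name, s, rec)
    # deterministic order: score desc, then name
    return sorted(scored.values(), key=lambda t: (-t[1], t[0]))


def map_one(query: str, lib: CompoundLibrary, prune: bool = True) -> MappingResult:
    if len(lib) == 0:
        raise ValueError("empty compound library")
    qnorm = normalize_name(query)
    rec = lib.by_name.get(qnorm)
    if rec is not None:
        return MappingResult(query=query, status="exact", matched_record=rec,
                             match_score=1.0)
    rec = lib.by_synonym.get(qnorm)
    if rec is not None:
        return MappingResult(query=query, status="synonym", matched_record=rec,
                             match_score=1.0)
    qid = str(query).strip().upper()
    if _HMDB_RE.match(qid) or _KEGG_RE.match(qid) or _PUBCHEM_RE.match(qid):
        rec = lib.by_id.get(qid)
        if rec is not None:
            return MappingResult(query=query, status="exact",
                                 matched_record=rec, match_score=1.0)
    ranked = _fuzzy_candidates(qnorm, lib, prune=prune)
    candidates = [(name, score) for name, score, _ in ranked[:N_CANDIDATES]]
    if ranked:
        name, score, rec = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0.0
        if score >= FUZZY_THRESHOLD and score - runner >= FUZZY_MARGIN:
            return MappingResult(query=query, status="fuzzy",
                                 matched_record=rec, match_score=score,
                                 candidates=candidates)
    return MappingResult(query=query, status="unmatched",
                         candidates=candidates)


def map_names(queries, lib: CompoundLibrary, prune: bool = True) -> list[MappingResult]:
    """Standardize a list of compound names/IDs against a library.

    Deterministic and per-query independent: results do not depend on the
    order or company of other queries.
    """
    if not queries:
        raise ValueError("no queries given")
    return [map_one(q, lib, prune=prune) for q in queries]


def convert_ids(ids, from_ns: str, to_ns: str, lib: CompoundLibrary) -> pd.DataFrame:
    """Exact-index conversion between identifier namespaces (no fuzzy)."""
    if from_ns not in NAMESPACES or to_ns not in NAMESPACES:
        raise ValueError(f"namespaces must be in {NAMESPACES}")
    if from_ns == to_ns:
        raise ValueError("from_ns and to_ns must differ")

    def _get(rec: CompoundRecord | None, ns: str):
        if rec is None:
            return None
        return {"hmdb": rec.hmdb_id, "kegg": rec.kegg_id,
                "pubchem": rec.pubchem_id, "name": rec.primary_name}[ns]

    rows = []
    for q in ids:
        if from_ns == "name":
            rec = lib.by_name.get(normalize_name(q))
        else:
            rec = lib.by_id.get(str(q).strip().upper())
            if rec is not None and _get(rec, from_ns) is None:
                rec = None
            elif rec is not None and \
                    str(_get(rec, from_ns)).upper() != str(q).strip().upper():
                rec = None
        rows.append({"query": q, from_ns: q if rec is None else _get(rec, from_ns),
                     to_ns: _get(rec, to_ns)})
    return pd.DataFrame(rows)
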