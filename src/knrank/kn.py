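"""Binary-weighted disease knowledge network: data model, weight schemes, TSV I/O.

The knowledge network (KN) is a strictly bipartite graph between diseases and
diagnostic findings.  Each disease--finding edge carries a *category* — how the
finding relates to that particular disease (an occasional manifestation, a
common manifestation, or an auxiliary examination result) — and a positive
weight.  Weights default to the value a :class:`WeightScheme` assigns to the
edge's category; an explicit per-edge weight overrides the scheme.

The category lives on the edge, not the finding node: the same symptom can be
a common manifestation of one disease and an occasional one of another, and
that asymmetry is precisely what lets the weight schemes differentiate
diagnoses.  When all edges of a finding agree, the finding has a well-defined
node-level category (see :meth:`KnowledgeNetwork.finding_category`).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "FindingCategory",
    "WeightScheme",
    "Edge",
    "KnowledgeNetwork",
    "Lexicon",
    "KNError",
    "KNFormatError",
    "KNValidationError",
    "scheme_from_label",
    "apply_scheme",
    "load_kn",
    "save_kn",
    "load_lexicon",
    "save_lexicon",
    "load_negation_cues",
    "lexicon_from_kn",
    "DEFAULT_NEGATION_CUES",
    "DEFAULT_SCHEME",
]


class KNError(Exception):
    """Base error for knowledge-network handling."""


class KNFormatError(KNError):
    """A KN/lexicon file could not be parsed; the message names the line."""


class KNValidationError(KNError):
    """A structural invariant of the network is violated."""


class FindingCategory(str, Enum):
    """How a finding relates to a disease.

    ``OCCASIONAL`` and ``COMMON`` are clinical manifestations (symptoms or
    signs) of low and medium diagnostic specificity; ``AUXILIARY`` is an
    instrument-based examination result, the strongest class of evidence.
    """

    OCCASIONAL = "occasional"
    COMMON = "common"
    AUXILIARY = "auxiliary"

    @classmethod
    def parse(cls, token: str) -> "FindingCategory":
        t = token.strip().lower()
        aliases = {
            "occasional": cls.OCCASIONAL,
            "occasional_manifestation": cls.OCCASIONAL,
            "common": cls.COMMON,
            "common_manifestation": cls.COMMON,
            "auxiliary": cls.AUXILIARY,
            "auxiliary_result": cls.AUXILIARY,
        }
        if t not in aliases:
            raise KNValidationError(
                f"unknown finding category {token!r}; expected one of "
                f"occasional, common, auxiliary"
            )
        return aliases[t]


@dataclass(frozen=True)
class WeightScheme:
    """Category-to-weight assignment for KN edges.

    The canonical schemes are written ``<ocA>`` with one digit per category,
    e.g. ``<137>`` = occasional 1, common 3, auxiliary 7 (the default).
    """

    occasional: float
    common: float
    auxiliary: float
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("occasional", "common", "auxiliary"):
            if not getattr(self, attr) > 0:
                raise KNValidationError(f"scheme weight {attr!r} must be > 0")

    def weight(self, category: FindingCategory) -> float:
        return {
            FindingCategory.OCCASIONAL: self.occasional,
            FindingCategory.COMMON: self.common,
            FindingCategory.AUXILIARY: self.auxiliary,
        }[category]


#: Named weight schemes: five graded settings plus the uniform baseline <111>.
NAMED_SCHEMES: dict[str, tuple[float, float, float]] = {
    "<111>": (1, 1, 1),
    "<113>": (1, 1, 3),
    "<123>": (1, 2, 3),
    "<135>": (1, 3, 5),
    "<137>": (1, 3, 7),
    "<139>": (1, 3, 9),
}


def scheme_from_label(label: str) -> WeightScheme:
    """Resolve a scheme label such as ``"<137>"`` or a comma triple ``"a,b,c"``.

    Raises :class:`KNValidationError` for unrecognized labels, listing the
    valid named schemes.
    """
    lab = label.strip()
    if lab in NAMED_SCHEMES:
        o, c, a = NAMED_SCHEMES[lab]
        return WeightScheme(o, c, a, name=lab)
    if "," in lab:
        parts = [p.strip() for p in lab.split(",")]
        if len(parts) == 3:
            try:
                o, c, a = (float(p) for p in parts)
            except ValueError:
                pass
            else:
                return WeightScheme(o, c, a, name=lab)
    raise KNValidationError(
        f"unrecognized weight scheme {label!r}; valid labels: "
        + ", ".join(sorted(NAMED_SCHEMES)) + ', or a comma triple "a,b,c"'
    )


DEFAULT_SCHEME = scheme_from_label("<137>")


@dataclass(frozen=True)
class Edge:
    """A finding-to-disease edge: the relation category and its weight."""

    category: FindingCategory
    weight: float

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise KNValidationError("edge weight must be > 0")


@dataclass
class KnowledgeNetwork:
    """Bipartite disease--finding network with per-edge categories and weights.

    ``diseases`` and ``findings`` map identifiers to display names; ``edges``
    maps ``(finding_id, disease_id)`` pairs to :class:`Edge`.  Identifier
    namespaces must be disjoint (strict bipartiteness).
    """

    diseases: dict[str, str] = field(default_factory=dict)
    findings: dict[str, str] = field(default_factory=dict)
    edges: dict[tuple[str, str], Edge] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def add_disease(self, disease_id: str, name: str | None = None) -> None:
        if disease_id in self.findings:
            raise KNValidationError(
                f"id {disease_id!r} already used as a finding; KN is bipartite"
            )
        existing = self.diseases.get(disease_id)
        if existing is not None and name is not None and existing != name:
            raise KNValidationError(
                f"conflicting names for disease {disease_id!r}: "
                f"{existing!r} vs {name!r}"
            )
        self.diseases.setdefault(disease_id, name if name is not None else disease_id)

    def add_finding(self, finding_id: str, name: str | None = None) -> None:
        if finding_id in self.diseases:
            raise KNValidationError(
                f"id {finding_id!r} already used as a disease; KN is bipartite"
            )
        existing = self.findings.get(finding_id)
        if existing is not None and name is not None and existing != name:
            raise KNValidationError(
                f"conflicting names for finding {finding_id!r}: "
                f"{existing!r} vs {name!r}"
            )
        self.findings.setdefault(finding_id, name if name is not None else finding_id)

    def add_edge(
        self,
        finding_id: str,
        disease_id: str,
        category: FindingCategory,
        weight: float | None = None,
        scheme: WeightScheme = DEFAULT_SCHEME,
    ) -> None:
        if finding_id not in self.findings:
            raise KNValidationError(f"edge endpoint {finding_id!r} is not a finding")
        if disease_id not in self.diseases:
            raise KNValidationError(f"edge endpoint {disease_id!r} is not a disease")
        key = (finding_id, disease_id)
        if key in self.edges:
            raise KNValidationError(f"duplicate edge {finding_id!r} -> {disease_id!r}")
        w = scheme.weight(category) if weight is None else weight
        self.edges[key] = Edge(category=category, weight=w)

    # -- queries ----------------------------------------------------------
    def diseases_of(self, finding_id: str) -> list[str]:
        """Disease identifiers adjacent to a finding."""
        return [d for (f, d) in self.edges if f == finding_id]

    def findings_of(self, disease_id: str) -> list[str]:
        return [f for (f, d) in self.edges if d == disease_id]

    def finding_outweight(self, finding_id: str) -> float:
        """Sum of edge weights leaving a finding (its out-weight)."""
        return sum(e.weight for (f, _d), e in self.edges.items() if f == finding_id)

    def finding_category(self, finding_id: str) -> FindingCategory | None:
        """The finding's category when all its edges agree, else ``None``."""
        cats = {e.category for (f, _d), e in self.edges.items() if f == finding_id}
        return cats.pop() if len(cats) == 1 else None

    def iter_edges(self) -> Iterator[tuple[str, str, Edge]]:
        for (f, d), e in self.edges.items():
            yield f, d, e

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check bipartiteness, endpoint existence, and weight positivity."""
        overlap = set(self.diseases) & set(self.findings)
        if overlap:
            raise KNValidationError(
                f"ids used as both disease and finding: {sorted(overlap)[:5]}"
            )
        for (f, d), e in self.edges.items():
            if f not in self.findings:
                raise KNValidationError(f"edge source {f!r} is not a known finding")
            if d not in self.diseases:
                raise KNValidationError(f"edge target {d!r} is not a known disease")
            if not e.weight > 0:
                raise KNValidationError(f"edge {f!r}->{d!r} has non-positive weight")


def apply_scheme(kn: KnowledgeNetwork, scheme: WeightScheme) -> KnowledgeNetwork:
    """Return a copy of *kn* with every edge reweighted from its category.

    Explicit per-edge weights are discarded; use this to compare weight
    schemes on the same network topology.
    """
    out = KnowledgeNetwork(dict(kn.diseases), dict(kn.findings), {})
    for (f, d), e in kn.edges.items():
        out.edges[(f, d)] = Edge(e.category, scheme.weight(e.category))
    return out


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

_KN_HEADER = ["finding_id", "finding_name", "category", "disease_id", "disease_name", "weight"]


def load_kn(path: str | Path, scheme: WeightScheme = DEFAULT_SCHEME) -> KnowledgeNetwork:
    """Read a KN from its TSV dialect.

    One edge per row; ``weight`` may be empty, in which case the row gets the
    weight *scheme* assigns to its category.  Lines starting with ``#`` are
    metadata comments and ignored.  Parse and validation errors name the
    offending line number.
    """
    kn = KnowledgeNetwork()
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header_seen = False
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if not header_seen:
                if [c.strip() for c in row[: len(_KN_HEADER)]] != _KN_HEADER:
                    raise KNFormatError(
                        f"{path}:{lineno}: bad header; expected "
                        + "\t".join(_KN_HEADER)
                    )
                header_seen = True
                continue
            if len(row) not in (5, 6):
                raise KNFormatError(
                    f"{path}:{lineno}: expected 5 or 6 tab-separated fields, got {len(row)}"
                )
            fid, fname, cat_tok, did, dname = (c.strip() for c in row[:5])
            wtok = row[5].strip() if len(row) == 6 else ""
            if not fid or not did:
                raise KNFormatError(f"{path}:{lineno}: empty finding_id or disease_id")
            try:
                category = FindingCategory.parse(cat_tok)
            except KNValidationError as exc:
                raise KNValidationError(f"{path}:{lineno}: {exc}") from None
            weight: float | None
            if wtok:
                try:
                    weight = float(wtok)
                except ValueError:
                    raise KNFormatError(
                        f"{path}:{lineno}: weight {wtok!r} is not a number"
                    ) from None
            else:
                weight = None
            try:
                kn.add_finding(fid, fname or None)
                kn.add_disease(did, dname or None)
                kn.add_edge(fid, did, category, weight, scheme)
            except KNValidationError as exc:
                raise KNValidationError(f"{path}:{lineno}: {exc}") from None
    kn.validate()
    return kn


def save_kn(kn: KnowledgeNetwork, path: str | Path, metadata: dict | None = None) -> None:
    """Write *kn* in the TSV dialect read by :func:`load_kn`.

    Weights are always written explicitly, so the round trip is exact under
    any scheme.  Optional *metadata* is written as ``# key=value`` comments.
    """
    kn.validate()
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if metadata:
            for k, v in metadata.items():
                fh.write(f"# {k}={v}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_KN_HEADER)
        for (f, d) in sorted(kn.edges):
            e = kn.edges[(f, d)]
            writer.writerow(
                [f, kn.findings[f], e.category.value, d, kn.diseases[d], repr(e.weight)]
            )


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

#: Small default negation-cue list for demos; real deployments should supply
#: the full cue dictionary for their language and institution.
DEFAULT_NEGATION_CUES: tuple[str, ...] = (
    "无", "未", "否认", "没有", "不", "未见", "无明显",
    "no", "not", "denies", "denied", "without", "negative",
)


@dataclass
class Lexicon:
    """Surface-form dictionary mapping text terms to KN finding ids."""

    entries: list[tuple[str, str]] = field(default_factory=list)
    negation_cues: list[str] = field(default_factory=lambda: list(DEFAULT_NEGATION_CUES))

    def __post_init__(self) -> None:
        for surface, fid in self.entries:
            if not surface:
                raise KNValidationError("lexicon surface terms must be non-empty")
            if not fid:
                raise KNValidationError(f"lexicon entry {surface!r} lacks a finding id")
        for cue in self.negation_cues:
            if not cue:
                raise KNValidationError("negation cues must be non-empty")

    def surfaces(self) -> list[str]:
        return [s for s, _ in self.entries]

    def surface_map(self) -> dict[str, str]:
        """surface -> finding_id; on collision the first entry wins."""
        out: dict[str, str] = {}
        for s, fid in self.entries:
            out.setdefault(s, fid)
        return out

    def validate_against(self, kn: KnowledgeNetwork) -> None:
        missing = sorted({fid for _, fid in self.entries} - set(kn.findings))
        if missing:
            raise KNValidationError(
                f"lexicon references unknown finding ids: {missing[:5]}"
            )


def lexicon_from_kn(
    kn: KnowledgeNetwork, negation_cues: Iterable[str] | None = None
) -> Lexicon:
    """Build a lexicon whose surfaces are the KN finding display names."""
    cues = list(negation_cues) if negation_cues is not None else list(DEFAULT_NEGATION_CUES)
    entries = sorted((name, fid) for fid, name in kn.findings.items())
    return Lexicon(entries=entries, negation_cues=cues)


def load_lexicon(
    path: str | Path, negation_path: str | Path | None = None
) -> Lexicon:
    """Read a ``surface<TAB>finding_id`` lexicon, optionally with a cue file."""
    entries: list[tuple[str, str]] = []
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise KNFormatError(
                    f"{path}:{lineno}: expected 'surface<TAB>finding_id'"
                )
            entries.append((parts[0], parts[1]))
    cues = (
        load_negation_cues(negation_path)
        if negation_path is not None
        else list(DEFAULT_NEGATION_CUES)
    )
    return Lexicon(entries=entries, negation_cues=cues)


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        for surface, fid in lexicon.entries:
            fh.write(f"{surface}\t{fid}\n")


def load_negation_cues(path: str | Path) -> list[str]:
    """One negation cue per line; blank lines and ``#`` comments ignored."""
    cues = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                cues.append(line)
    return cues
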