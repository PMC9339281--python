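"""Consensus R-loop-binding-protein sets from proteomic screen hit lists.

Published R-loop interactome screens disagree substantially, so a consensus
positive class is built by intersecting several hit lists: either the strict
core found in *all* studies (``all_k``), the union of all pairwise
intersections (``any_pair``, i.e. "found in at least two studies"), or a
generic ``k_of_n`` membership rule.  Membership is set-based: a protein
reported twice inside one study counts once.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

RULES = ("all_k", "any_pair", "k_of_n")


def normalize_ids(raw_list: Sequence[str], mode: str = "uppercase") -> set[str]:
    """Normalize a raw list of protein identifiers into a deduplicated set.

    Parameters
    ----------
    raw_list:
        Identifiers as read from a file; may contain surrounding whitespace,
        mixed case and duplicates.
    mode:
        ``"uppercase"`` — strip whitespace and uppercase (gene-symbol style).
        ``"strip_version"`` — additionally drop a trailing ``.N`` version
        suffix (accession style, e.g. ``P38398.2`` → ``P38398``).

    Counts depend on the identifier namespace of the input lists; mixing
    gene symbols with accessions across lists will silently deflate overlaps.
    """
    if mode not in ("uppercase", "strip_version"):
        raise ValueError(f"unknown normalization mode: {mode!r}")
    cleaned = []
    for item in raw_list:
        token = item.strip().upper()
        if not token:
            continue
        if mode == "strip_version":
            stem, dot, suffix = token.rpartition(".")
            if dot and suffix.isdigit():
                token = stem
        cleaned.append(token)
    if not cleaned:
        raise ValueError("empty hit list")
    members = set(cleaned)
    n_dup = len(cleaned) - len(members)
    if n_dup:
        log.info("normalize_ids: removed %d duplicate identifiers", n_dup)
    return members


@dataclass(frozen=True)
class HitList:
    """One proteomic screen's hit list: a label plus a normalized ID set."""

    study_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"hit list {self.study_name!r} is empty")
        object.__setattr__(self, "members", frozenset(self.members))

    @classmethod
    def from_ids(cls, study_name: str, raw_ids: Sequence[str],
                 mode: str = "uppercase") -> "HitList":
        return cls(study_name, frozenset(normalize_ids(raw_ids, mode)))

    @classmethod
    def from_file(cls, path: str | Path, study_name: str | None = None,
                  mode: str = "uppercase") -> "HitList":
        """Read a hit list: one ID per line, or a TSV with an ``id`` column."""
        path = Path(path)
        lines = path.read_text().splitlines()
        if not lines:
            raise ValueError(f"empty hit list file: {path}")
        header = lines[0].rstrip("\n").split("\t")
        if "id" in [h.strip().lower() for h in header] and len(header) > 1 or \
                header[0].strip().lower() == "id":
            idx = [h.strip().lower() for h in header].index("id")
            ids = [ln.split("\t")[idx] for ln in lines[1:] if ln.strip()]
        else:
            ids = [ln for ln in lines if ln.strip()]
        return cls.from_ids(study_name or path.stem, ids, mode)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ConsensusSet:
    """A consensus positive-class set with per-member study provenance."""

    name: str
    members: set[str]
    rule: str
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.provenance) != self.members:
            raise ValueError("provenance must cover exactly the members")

    def __len__(self) -> int:
        return len(self.members)

    def to_tsv(self, path: str | Path) -> None:
        """Write ``id<TAB>n_studies<TAB>studies`` rows, sorted by id."""
        with open(path, "w") as fh:
            fh.write("id\tn_studies\tstudies\n")
            for member in sorted(self.members):
                studies = self.provenance[member]
                fh.write(f"{member}\t{len(studies)}\t{','.join(studies)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "ConsensusSet":
        path = Path(path)
        members: set[str] = set()
        prov: dict[str, list[str]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:1] != ["id"]:
                raise ValueError(f"malformed consensus file header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                members.add(fields[0])
                prov[fields[0]] = fields[2].split(",") if len(fields) > 2 else []
        return cls(name or path.stem, members, "loaded", prov)


def intersect_consensus(lists: Sequence[HitList], rule: str = "all_k",
                        k: int | None = None,
                        name: str | None = None) -> ConsensusSet:
    """Intersect screen hit lists under an overlap rule.

    ``all_k`` keeps proteins present in every list; ``any_pair`` keeps
    proteins present in at least two lists (the union of all pairwise
    intersections, which contains the all-``k`` core); ``k_of_n`` keeps
    proteins present in at least ``k`` lists.  The result is invariant to
    the order of the input lists.
    """
    if len(lists) < 2:
        raise ValueError("need at least two hit lists to build a consensus")
    if rule not in RULES:
        raise ValueError(f"unknown rule: {rule!r} (expected one of {RULES})")
    if rule == "k_of_n":
        if k is None or not 1 <= k <= len(lists):
            raise ValueError(f"k_of_n rule needs 1 <= k <= {len(lists)}")
        required = k
    elif rule == "all_k":
        required = len(lists)
    else:  # any_pair
        required = 2

    counts: dict[str, list[str]] = {}
    for hl in lists:
        for member in hl.members:
            counts.setdefault(member, []).append(hl.study_name)
    members = {m for m, studies in counts.items() if len(studies) >= required}
    provenance = {m: sorted(counts[m]) for m in members}
    if rule == "any_pair":
        # sanity: identical to the explicit union of pairwise intersections
        pairwise = set().union(*(
            a.members & b.members for a, b in itertools.combinations(lists, 2)
        )) if len(lists) >= 2 else set()
        assert members == pairwise
    set_name = name or f"consensus_{rule}"
    log.info("intersect_consensus(%s): %d lists -> %d members",
             rule, len(lists), len(members))
    return ConsensusSet(set_name, members, rule, provenance)


def overlap_stats(set_a: Iterable[str], set_b: Iterable[str],
                  background_size: int):
    """2x2 overlap contingency table and two-sided Fisher exact p-value.

    The table counts (in-both, a-only, b-only, neither) against a background
    of ``background_size`` proteins from which both sets are drawn.
    """
    from . import stats  # local import: avoid cycle at module import time

    a, b = set(set_a), set(set_b)
    union = a | b
    if background_size < len(union):
        raise ValueError(
            f"background_size {background_size} smaller than |a ∪ b| = {len(union)}")
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = background_size - len(union)
    return stats.fisher_exact(both, a_only, b_only, neither)
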