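"""Protein descriptor computation and annotation ingest.

Two kinds of descriptors feed the classifier:

* sequence-intrinsic — length, GRAVY (Kyte-Doolittle grand average of
  hydropathy), aliphatic index (Ikai), charged-residue percentages and the
  20-way amino-acid composition, all computed here from FASTA;
* annotation-derived — abundance (PaxDB-style ppm), disorder %, LCR %,
  CamSol solubility, PScore, phosphosite counts, nucleic-acid-binding
  membership and Pfam-style domain hits, ingested from TSV tables produced
  by external tools.

The classifier consumes a complete-case table of exactly 30 features:
length, GRAVY, aliphatic index, abundance, CamSol, disorder %, LCR %,
PScore, nucleic-acid binding (0/1), phosphosite % and the 20 composition
percentages.  Charged-residue percentages are computed for distribution
comparisons between protein sets but are not classifier inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Kyte & Doolittle (1982) hydropathy scale, J Mol Biol 157:105-132.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# D/E/K/R only; histidine is not counted as charged.
CHARGED = set("DEKR")
POSITIVE = set("KR")
NEGATIVE = set("DE")

COMPOSITION_COLUMNS = [f"comp_{aa}" for aa in STANDARD_AA]

#: Classifier schema: the 30 feature columns, fixed order.
FEATURE_COLUMNS = [
    "length", "gravy", "aliphatic_index", "abundance", "camsol",
    "disorder_pct", "lcr_pct", "pscore", "nucleic_acid_binding",
    "phosphosite_pct",
] + COMPOSITION_COLUMNS

ANNOTATION_FEATURES = ["abundance", "camsol", "disorder_pct", "lcr_pct", "pscore"]


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: identifier, sequence and a nonstandard-letter flag."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def nonstandard(self) -> bool:
        return any(c not in KYTE_DOOLITTLE for c in self.sequence)


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain: str
    e_value: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError(f"negative E-value for {self.protein_id}/{self.domain}")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein FASTA; the first whitespace-delimited header token is
    the identifier (uppercased)."""
    records = [ProteinRecord(rec.id.upper(), str(rec.seq))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    for i, c in enumerate(sequence):
        if c not in KYTE_DOOLITTLE:
            raise ValueError(f"nonstandard residue {c!r} at position {i + 1}")
    return sequence


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue.

    Negative values indicate hydrophilic proteins; bounded by the scale
    extremes [-4.5 (Arg), 4.5 (Ile)].
    """
    sequence = _check_sequence(sequence)
    return sum(KYTE_DOOLITTLE[c] for c in sequence) / len(sequence)


def aliphatic_index(sequence: str) -> float:
    """Ikai aliphatic index: X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)),
    with X the mole percent of each residue.  Range [0, 390]."""
    sequence = _check_sequence(sequence)
    n = len(sequence)
    x = {aa: 100.0 * sequence.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def charged_pct(sequence: str) -> float:
    """Percent of residues that are charged (D, E, K, R; His excluded)."""
    sequence = _check_sequence(sequence)
    return 100.0 * sum(c in CHARGED for c in sequence) / len(sequence)


def positive_pct(sequence: str) -> float:
    """Percent of positively charged residues (K, R)."""
    sequence = _check_sequence(sequence)
    return 100.0 * sum(c in POSITIVE for c in sequence) / len(sequence)


def negative_pct(sequence: str) -> float:
    """Percent of negatively charged residues (D, E)."""
    sequence = _check_sequence(sequence)
    return 100.0 * sum(c in NEGATIVE for c in sequence) / len(sequence)


def aa_composition(sequence: str) -> dict[str, float]:
    """Per-residue composition in percent, keyed by amino acid in
    alphabetical one-letter order; values sum to 100."""
    sequence = _check_sequence(sequence)
    n = len(sequence)
    return {aa: 100.0 * sequence.count(aa) / n for aa in STANDARD_AA}


def sequence_features(records: Iterable[ProteinRecord],
                      drop_nonstandard: bool = True) -> pd.DataFrame:
    """Sequence-intrinsic descriptor table, indexed by protein id.

    Proteins containing letters outside the 20 standard amino acids (U, B,
    Z, X, \\*) are dropped with a logged count, mirroring the treatment of
    such sequences by sequence-based solubility predictors.
    Includes the classifier columns plus charged/positive/negative percent.
    """
    rows = []
    n_nonstandard = 0
    for rec in records:
        if rec.nonstandard:
            n_nonstandard += 1
            if not drop_nonstandard:
                raise ValueError(f"nonstandard residues in {rec.id}")
            continue
        row = {
            "id": rec.id,
            "length": rec.length,
            "gravy": gravy(rec.sequence),
            "aliphatic_index": aliphatic_index(rec.sequence),
            "charged_pct": charged_pct(rec.sequence),
            "positive_pct": positive_pct(rec.sequence),
            "negative_pct": negative_pct(rec.sequence),
        }
        row.update({f"comp_{aa}": v for aa, v in aa_composition(rec.sequence).items()})
        rows.append(row)
    if n_nonstandard:
        log.info("sequence_features: dropped %d nonstandard-letter sequences",
                 n_nonstandard)
    if not rows:
        raise ValueError("no standard-letter sequences to featurize")
    return pd.DataFrame(rows).set_index("id")


def filter_domain_hits(hits: Sequence[DomainHit], lengths: Mapping[str, int],
                       e_max: float = 0.001, max_len: int = 5000) -> pd.DataFrame:
    """Filter Pfam-style domain hits and count domains per protein.

    Hits with ``e_value >= e_max`` are discarded; proteins longer than
    ``max_len`` residues are excluded from the domain analysis entirely.
    Returns a frame indexed by protein id with ``n_domains`` (distinct
    domain names passing the filter) and ``n_hits`` (total passing hits).
    """
    missing = sorted({h.protein_id for h in hits} - set(lengths))
    if missing:
        raise ValueError(f"missing lengths for: {', '.join(missing)}")
    domains: dict[str, set[str]] = {}
    totals: dict[str, int] = {}
    n_len_excluded = 0
    seen_long = set()
    for h in hits:
        if lengths[h.protein_id] > max_len:
            if h.protein_id not in seen_long:
                seen_long.add(h.protein_id)
                n_len_excluded += 1
            continue
        if h.e_value >= e_max:
            continue
        domains.setdefault(h.protein_id, set()).add(h.domain)
        totals[h.protein_id] = totals.get(h.protein_id, 0) + 1
    if n_len_excluded:
        log.info("filter_domain_hits: excluded %d proteins longer than %d aa",
                 n_len_excluded, max_len)
    ids = sorted(domains)
    return pd.DataFrame(
        {"n_domains": [len(domains[i]) for i in ids],
         "n_hits": [totals[i] for i in ids]},
        index=pd.Index(ids, name="id"),
    )


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read ``id<TAB>domain<TAB>evalue`` rows (header optional)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and parts[0].strip().lower() == "id":
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            try:
                e_val = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric E-value") from exc
            hits.append(DomainHit(parts[0].strip().upper(), parts[1].strip(), e_val))
    return hits


def _read_value_table(path: str | Path, value_column: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    cols = [c.strip().lower() for c in df.columns]
    if "id" not in cols:
        raise ValueError(f"{path}: no 'id' column in header {list(df.columns)}")
    df.columns = cols
    value_cols = [c for c in cols if c != "id"]
    if len(value_cols) != 1:
        raise ValueError(f"{path}: expected exactly one value column, got {value_cols}")
    values = pd.to_numeric(df[value_cols[0]], errors="coerce")
    bad = values.isna() & df[value_cols[0]].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header +1-based
        raise ValueError(f"{path}: non-numeric value at row {row}")
    return pd.Series(values.to_numpy(),
                     index=df["id"].astype(str).str.strip().str.upper(),
                     name=value_column)


def ingest_annotations(tables: Mapping[str, str | Path],
                       nucleic_acid_list: Iterable[str],
                       lengths: Mapping[str, int],
                       phosphosite_encoding: str = "density") -> pd.DataFrame:
    """Join annotation TSVs into per-protein feature columns.

    Parameters
    ----------
    tables:
        Maps feature name (``abundance``, ``camsol``, ``disorder_pct``,
        ``lcr_pct``, ``pscore``, ``phosphosites``) to a two-column TSV
        (``id<TAB>value``).  ``phosphosites`` holds annotated site counts.
    nucleic_acid_list:
        Identifiers of proteins annotated as nucleic-acid binding; the
        binary feature is 1 iff a protein appears here.
    lengths:
        Residue counts, needed to convert phosphosite counts to a
        per-100-residue density.
    phosphosite_encoding:
        ``"density"`` — 100 * sites / length (default); ``"binary"`` — 1 iff
        at least one annotated site.

    Abundance stays in ppm as supplied; no log transform is applied (the
    forest is invariant to monotone feature transforms).
    """
    if phosphosite_encoding not in ("density", "binary"):
        raise ValueError(f"unknown phosphosite encoding: {phosphosite_encoding!r}")
    columns = {}
    for feature in ANNOTATION_FEATURES:
        if feature in tables:
            columns[feature] = _read_value_table(tables[feature], feature)
    joined = pd.DataFrame(columns)
    if "phosphosites" in tables:
        sites = _read_value_table(tables["phosphosites"], "phosphosites")
        if phosphosite_encoding == "binary":
            pct = (sites > 0).astype(float)
        else:
            lens = pd.Series({k.upper(): v for k, v in lengths.items()})
            pct = 100.0 * sites / lens.reindex(sites.index)
        joined["phosphosite_pct"] = pct
    na_set = {str(x).strip().upper() for x in nucleic_acid_list}
    joined["nucleic_acid_binding"] = [
        1 if pid in na_set else 0 for pid in joined.index
    ]
    joined.index.name = "id"
    return joined


def build_feature_table(records: Iterable[ProteinRecord],
                        annotations: pd.DataFrame,
                        positives: Iterable[str],
                        phosphosite_encoding: str = "density") -> pd.DataFrame:
    """Assemble the labeled complete-case 30-feature classifier table.

    A protein is kept only if every one of the 30 features is present:
    sequence-derived features require a standard-letter sequence, and each
    annotation column must be non-missing.  The ``label`` column is 1 iff
    the id is in ``positives``.  Raises if no positive survives filtering.
    """
    seq_feats = sequence_features(records)
    table = seq_feats.join(annotations, how="left")
    missing_cols = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"annotations missing feature columns: {missing_cols}")
    n_before = len(table)
    table = table.dropna(subset=FEATURE_COLUMNS)
    n_dropped = n_before - len(table)
    if n_dropped:
        log.info("build_feature_table: dropped %d incomplete rows "
                 "(complete-case filter)", n_dropped)
    pos = {str(p).strip().upper() for p in positives}
    table = table[FEATURE_COLUMNS].copy()
    table["label"] = [1 if pid in pos else 0 for pid in table.index]
    if int(table["label"].sum()) == 0:
        raise ValueError("positive class empty after complete-case filtering")
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the feature table as TSV with the fixed column order."""
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=True, index_label="id",
                               float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
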