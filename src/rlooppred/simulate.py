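"""Synthetic labeled proteomes with a controllable class-separation dial.

The generator emulates the shape of the real inputs — a FASTA proteome,
per-protein annotation tables (abundance in ppm, disorder %, LCR %, CamSol,
PScore, phosphosite counts, a nucleic-acid-binding membership list, and a
per-class Poisson domain-count column) plus ground-truth labels — with the
class-conditional shifts observed for real RLBPs: positives are longer,
more charged (hence lower GRAVY and aliphatic index), more disordered,
more abundant and more often annotated as nucleic-acid binding.

``effect_size`` is the standardized mean shift (positive minus negative,
in negative-class SD units) applied to the continuous annotation features;
sequence composition is tilted proportionally (charged residues up,
aliphatic residues down).  At ``effect_size = 0`` with equal binding rates
the two classes are exchangeable, giving a proper null.

The generator never calls the classifier: parameter-recovery tests stay
honest because the only link between simulation and model is the feature
table produced by the real featurizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import features as ft

# Approximate human proteome residue frequencies (percent).
BASE_FREQS = {
    "A": 7.0, "C": 2.3, "D": 4.7, "E": 7.1, "F": 3.7, "G": 6.6, "H": 2.6,
    "I": 4.3, "K": 5.7, "L": 10.0, "M": 2.1, "N": 3.6, "P": 6.3, "Q": 4.8,
    "R": 5.6, "S": 8.3, "T": 5.4, "V": 6.0, "W": 1.2, "Y": 2.7,
}

# Negative-class distributions for the annotation features:
# (mean, sd) on the sampling scale; abundance is sampled log-normally.
ANNOTATION_PARAMS = {
    "log_abundance": (2.5, 1.5),   # ln ppm
    "disorder_pct": (30.0, 12.0),
    "lcr_pct": (10.0, 6.0),
    "camsol": (0.0, 1.0),
    "pscore": (0.0, 1.5),
}

PHOSPHOSITE_RATE = 0.02         # expected annotated sites per residue
DOMAIN_POISSON = (3.0, 1.0)     # (positive, negative) mean domain count
COMPOSITION_TILT = 0.05         # per-unit-effect relative frequency tilt


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic proteome."""

    n_pos: int = 100
    n_neg: int = 1000
    effect_size: float | Mapping[str, float] = 2.0
    nucleic_binding_rates: tuple[float, float] = (0.8, 0.1)
    length_range: tuple[int, int] = (80, 1200)
    seed: int = 0
    missingness: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be positive")
        if self.length_range[0] < 1:
            raise ValueError("length_range minimum must be >= 1")
        p_pos, p_neg = self.nucleic_binding_rates
        if not (0 <= p_pos <= 1 and 0 <= p_neg <= 1):
            raise ValueError("binding rates must lie in [0, 1]")
        for rate in self.missingness.values():
            if not 0 <= rate < 1:
                raise ValueError("missingness rates must lie in [0, 1)")

    def effect(self, feature: str) -> float:
        if isinstance(self.effect_size, Mapping):
            return float(self.effect_size.get(feature, 0.0))
        return float(self.effect_size)


def _class_frequencies(effect: float) -> np.ndarray:
    """Positive-class residue frequencies: charged up, aliphatic down."""
    freqs = np.array([BASE_FREQS[aa] for aa in ft.STANDARD_AA], dtype=float)
    tilt = COMPOSITION_TILT * effect
    for i, aa in enumerate(ft.STANDARD_AA):
        if aa in ft.CHARGED:
            freqs[i] *= 1.0 + tilt
        elif aa in "AVIL":
            freqs[i] *= max(0.0, 1.0 - tilt)
    return freqs / freqs.sum()


def generate_sequences(spec: SyntheticSpec) -> tuple[list[ft.ProteinRecord], pd.Series]:
    """Random protein records with class-dependent residue frequencies.

    Lengths are normal around the midpoint of ``length_range`` (SD a fifth
    of the span), with the positive-class mean shifted up by half an
    effect-size SD; clipped to the range.  Returns (records, labels).
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(ft.STANDARD_AA))
    neg_freqs = _class_frequencies(0.0)
    pos_freqs = _class_frequencies(spec.effect("composition"))
    lo, hi = spec.length_range
    mu, sigma = (lo + hi) / 2.0, (hi - lo) / 5.0
    records: list[ft.ProteinRecord] = []
    labels = {}
    n_total = spec.n_pos + spec.n_neg
    width = len(str(n_total))
    for i in range(n_total):
        is_pos = i < spec.n_pos
        shift = 0.5 * spec.effect("length") * sigma if is_pos else 0.0
        length = int(np.clip(rng.normal(mu + shift, sigma), lo, hi))
        freqs = pos_freqs if is_pos else neg_freqs
        seq = "".join(rng.choice(alphabet, size=length, p=freqs))
        pid = f"PROT{i + 1:0{width}d}"
        records.append(ft.ProteinRecord(pid, seq))
        labels[pid] = 1 if is_pos else 0
    return records, pd.Series(labels, name="label")


def generate_annotations(records: list[ft.ProteinRecord], labels: pd.Series,
                         spec: SyntheticSpec) -> pd.DataFrame:
    """Class-conditionally shifted annotation columns for ``records``.

    Continuous features are normal (log-normal for abundance, where the
    shift is applied on the log scale) with the positive-class mean moved
    by ``effect_size`` negative-class SDs; percentages are clipped to
    [0, 100].  The nucleic-acid-binding flag is Bernoulli with the
    class-specific rate; phosphosite counts are Poisson with a per-residue
    rate inflated for positives; domain counts are per-class Poisson.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ids = [r.id for r in records]
    is_pos = labels.reindex(ids).to_numpy() == 1
    n = len(ids)
    out = pd.DataFrame(index=pd.Index(ids, name="id"))

    for feature, (mean, sd) in ANNOTATION_PARAMS.items():
        name = "abundance" if feature == "log_abundance" else feature
        shift = spec.effect(name) * sd
        values = rng.normal(mean + np.where(is_pos, shift, 0.0), sd)
        if feature == "log_abundance":
            values = np.exp(values)
        elif name.endswith("_pct"):
            values = np.clip(values, 0.0, 100.0)
        out[name] = values

    lengths = np.array([r.length for r in records], dtype=float)
    rate = PHOSPHOSITE_RATE * (1.0 + 0.3 * np.where(
        is_pos, spec.effect("phosphosite_pct"), 0.0))
    out["phosphosites"] = rng.poisson(rate * lengths)

    p_pos, p_neg = spec.nucleic_binding_rates
    out["nucleic_acid_binding"] = rng.binomial(
        1, np.where(is_pos, p_pos, p_neg))

    lam_pos, lam_neg = DOMAIN_POISSON
    out["n_domains"] = rng.poisson(np.where(is_pos, lam_pos, lam_neg))

    for feature, rate in spec.missingness.items():
        mask = rng.random(n) < rate
        out.loc[mask, feature] = np.nan
    return out


def _ingest_frame(annotations: pd.DataFrame, lengths: Mapping[str, int]) -> pd.DataFrame:
    """Annotation columns in the schema the featurizer joins on."""
    frame = annotations[ft.ANNOTATION_FEATURES].copy()
    lens = pd.Series(lengths).reindex(annotations.index)
    frame["phosphosite_pct"] = 100.0 * annotations["phosphosites"] / lens
    frame["nucleic_acid_binding"] = annotations["nucleic_acid_binding"]
    return frame


def make_benchmark(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a proteome and run the production featurizer on it.

    Returns the labeled 30-feature complete-case table (as consumed by the
    ensemble) and the ground-truth labels for every generated protein,
    including any dropped by the complete-case filter.
    """
    records, labels = generate_sequences(spec)
    annotations = generate_annotations(records, labels, spec)
    lengths = {r.id: r.length for r in records}
    positives = set(labels.index[labels == 1])
    table = ft.build_feature_table(records, _ingest_frame(annotations, lengths),
                                   positives)
    return table, labels


def make_hit_lists(regions: Mapping[tuple[str, ...], int],
                   prefix: str = "G") -> list:
    """Build screen hit lists with an exact prescribed overlap structure.

    ``regions`` maps a tuple of study names to the number of proteins
    found in exactly those studies (a Venn-region count).  Distinct ids
    are generated per region, so every intersection cardinality is exact
    by construction.  Returns one :class:`~rlooppred.consensus.HitList`
    per study name mentioned.
    """
    from .consensus import HitList

    studies: dict[str, set[str]] = {}
    counter = 0
    for names, count in regions.items():
        if count < 0:
            raise ValueError("region counts must be non-negative")
        for _ in range(count):
            counter += 1
            pid = f"{prefix}{counter:05d}"
            for name in names:
                studies.setdefault(name, set()).add(pid)
    return [HitList(name, frozenset(members))
            for name, members in studies.items()]


def write_simulation(spec: SyntheticSpec, outdir: str | Path,
                     n_studies: int = 3, study_noise: float = 0.05) -> dict[str, Path]:
    """Write a full synthetic input bundle in the dialects the pipeline reads.

    Emits ``proteome.fasta``, one two-column TSV per annotation feature,
    the nucleic-acid-binding membership list, domain hits, ground-truth
    labels, and ``n_studies`` synthetic screen hit lists (each: every true
    positive plus a ``study_noise`` fraction of negatives) so the consensus
    stage can be exercised end to end.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, labels = generate_sequences(spec)
    annotations = generate_annotations(records, labels, spec)
    paths: dict[str, Path] = {}

    fasta = outdir / "proteome.fasta"
    with open(fasta, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i:i + 60] + "\n")
    paths["proteome"] = fasta

    for feature in ["abundance", "disorder_pct", "lcr_pct", "camsol",
                    "pscore", "phosphosites"]:
        path = outdir / f"{feature}.tsv"
        col = annotations[feature].dropna()
        col.to_frame().to_csv(path, sep="\t", index_label="id",
                              float_format="%.10g")
        paths[feature] = path

    na_path = outdir / "nucleic_binding.txt"
    binders = annotations.index[annotations["nucleic_acid_binding"] == 1]
    na_path.write_text("".join(f"{pid}\n" for pid in binders))
    paths["nucleic_acid_list"] = na_path

    dom_path = outdir / "domains.tsv"
    rng = np.random.default_rng(spec.seed + 2)
    with open(dom_path, "w") as fh:
        fh.write("id\tdomain\tevalue\n")
        for pid, count in annotations["n_domains"].items():
            for j in range(int(count)):
                fh.write(f"{pid}\tDOM{j + 1}\t{rng.uniform(1e-10, 1e-4):.3e}\n")
    paths["domains"] = dom_path

    labels_path = outdir / "labels.tsv"
    labels.to_frame().to_csv(labels_path, sep="\t", index_label="id")
    paths["labels"] = labels_path

    positives = list(labels.index[labels == 1])
    negatives = np.array(labels.index[labels == 0])
    for s in range(n_studies):
        study_rng = np.random.default_rng(spec.seed + 10 + s)
        noise = study_rng.choice(
            negatives, size=int(round(study_noise * len(negatives))),
            replace=False)
        members = sorted(set(positives) | set(noise))
        path = outdir / f"study{s + 1}.txt"
        path.write_text("".join(f"{m}\n" for m in members))
        paths[f"study{s + 1}"] = path
    return paths
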