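"""Raw small-RNA reads -> normalized sncRNA count matrix.

Pipeline: 3' adapter trimming and a 17-nt length floor, collapsing of
identical sequences, annotation against the reference bundle with an
isomiR-tolerant miRNA rule, priority-based class assignment, size-factor
(median-of-ratios) normalization, and an expressed-miRNA filter.

The miRNA counting rule: a read counts toward a mature miRNA iff it starts
exactly at the mature 5' site on the precursor, matches the precursor with no
internal mismatches, and its 3' end falls within 3 nt of the annotated mature
3' end — trimmings shorten into the mature sequence, extensions must copy the
precursor (templated isomiRs only).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import OTHERS, RNA_CLASSES, ReferenceBundle, SncRnaReference

MIN_READ_LENGTH = 17
ISOMIR_SLACK = 3  # maximum 3' trimming/extension in nt


# --------------------------------------------------------------------------
# Trimming, filtering, collapsing
# --------------------------------------------------------------------------


@dataclass
class TrimLog:
    """Per-reason counts of reads discarded by :func:`trim_and_filter`."""

    kept: int = 0
    no_adapter: int = 0
    too_short: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.no_adapter + self.too_short


def _find_adapter(
    read: str, adapter: str, min_length: int, min_overlap: int = 3
) -> int | None:
    """Return the trim position: the start of the best 3' adapter occurrence.

    The adapter is located by exact prefix match — the longest prefix of the
    adapter occurring at position >= min_length (the adapter may run off the
    read end); ties broken toward the earliest position. Matches shorter than
    ``min_overlap`` are ignored so chance 1-2 nt suffix agreement does not
    clip adapterless reads. None if absent.
    """
    best_len, best_pos = min_overlap - 1, None
    n = len(read)
    for pos in range(min_length, n):
        m = min(len(adapter), n - pos)
        if m > best_len and read[pos : pos + m] == adapter[:m]:
            best_len, best_pos = m, pos
    return best_pos


def trim_and_filter(
    reads,
    adapter: str | None,
    min_length: int = MIN_READ_LENGTH,
    require_adapter: bool = True,
):
    """Clip the 3' adapter and drop short / adapterless reads.

    Parameters
    ----------
    reads : iterable of str
        Raw read sequences (DNA alphabet).
    adapter : str or None
        3' adapter sequence. ``None`` disables trimming (pre-trimmed input).
    min_length : int
        Reads shorter than this after trimming are discarded.
    require_adapter : bool
        When an adapter is given, discard reads without an adapter occurrence
        (set False to keep them untrimmed, for mixed input).

    Returns
    -------
    (list of str, TrimLog)
    """
    if adapter is not None and not adapter:
        raise ValueError("adapter must be non-empty when adapter mode is enabled")
    kept: list[str] = []
    log = TrimLog()
    for read in reads:
        read = read.upper()
        if adapter is not None:
            pos = _find_adapter(read, adapter, min_length)
            if pos is None:
                if require_adapter:
                    log.no_adapter += 1
                    continue
            else:
                read = read[:pos]
        if len(read) < min_length:
            log.too_short += 1
            continue
        kept.append(read)
        log.kept += 1
    return kept, log


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its multiplicity."""

    sequence: str
    multiplicity: int


def collapse_reads(reads) -> list[CollapsedRead]:
    """Collapse identical sequences into (sequence, multiplicity) records."""
    counts = Counter(reads)
    return [CollapsedRead(seq, n) for seq, n in counts.items()]


# --------------------------------------------------------------------------
# Matching and classification
# --------------------------------------------------------------------------


def count_mirna_match(read_sequence: str, reference: SncRnaReference) -> bool:
    """Isomir-tolerant mature-anchored miRNA matching rule.

    True iff the read starts exactly at the mature 5' start site on the
    precursor, matches the precursor exactly from there, and its 3' end lies
    within ``mature_end ± 3``; 3' extensions must be precursor-templated.
    """
    if reference.rna_class != "miRNA":
        raise ValueError("count_mirna_match requires a miRNA reference")
    if reference.precursor_sequence is None:
        raise ValueError("miRNA reference lacks precursor")
    mature_len = reference.mature_end - reference.mature_start
    read_len = len(read_sequence)
    if not (mature_len - ISOMIR_SLACK <= read_len <= mature_len + ISOMIR_SLACK):
        return False
    end = reference.mature_start + read_len
    if end > len(reference.precursor_sequence):
        return False
    return reference.precursor_sequence[reference.mature_start : end] == read_sequence


def _hamming_contains(haystack: str, needle: str, max_mismatches: int) -> bool:
    n, m = len(haystack), len(needle)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(haystack[i : i + m], needle):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            return True
    return False


class ReadMatcher:
    """Matches collapsed reads against a reference bundle.

    miRNAs are indexed by the first k nucleotides downstream of the mature 5'
    site on the precursor, so the anchored rule is a dictionary probe plus a
    string comparison; other classes use substring containment.
    """

    ANCHOR_K = 12  # < shortest post-filter read (17 nt)

    def __init__(self, bundle: ReferenceBundle, max_mismatches: int = 0):
        self.bundle = bundle
        self.max_mismatches = max_mismatches
        self._mirna_index: dict[str, list[SncRnaReference]] = {}
        for ref in bundle.by_class("miRNA"):
            key = ref.precursor_sequence[
                ref.mature_start : ref.mature_start + self.ANCHOR_K
            ]
            self._mirna_index.setdefault(key, []).append(ref)
        self._other_refs = {
            cls: bundle.by_class(cls) for cls in RNA_CLASSES if cls != "miRNA"
        }

    def match_read(self, read) -> dict[str, list[str]]:
        """Return matching feature ids grouped by RNA class."""
        seq = read.sequence if isinstance(read, CollapsedRead) else read
        candidates: dict[str, list[str]] = {}
        mirna_hits = [
            ref.feature_id
            for ref in self._mirna_index.get(seq[: self.ANCHOR_K], [])
            if count_mirna_match(seq, ref)
        ]
        if mirna_hits:
            candidates["miRNA"] = mirna_hits
        for cls, refs in self._other_refs.items():
            if self.max_mismatches == 0:
                hits = [r.feature_id for r in refs if seq in r.sequence]
            else:
                hits = [
                    r.feature_id
                    for r in refs
                    if _hamming_contains(r.sequence, seq, self.max_mismatches)
                ]
            if hits:
                candidates[cls] = hits
        return candidates


def match_read(
    read, bundle: ReferenceBundle, max_mismatches: int = 0
) -> dict[str, list[str]]:
    """One-shot convenience wrapper around :class:`ReadMatcher`."""
    return ReadMatcher(bundle, max_mismatches).match_read(read)


@dataclass(frozen=True)
class AnnotationRecord:
    """Class assignment and per-feature weights for one collapsed read."""

    sequence: str
    multiplicity: int
    assigned_class: str
    weights: dict[str, float] = field(default_factory=dict)


def classify_read(read: CollapsedRead, candidates: dict[str, list[str]]) -> AnnotationRecord:
    """Assign the highest-priority matching class; split weight 1/k inside it."""
    for cls in RNA_CLASSES:
        features = candidates.get(cls)
        if features:
            w = 1.0 / len(features)
            return AnnotationRecord(
                sequence=read.sequence,
                multiplicity=read.multiplicity,
                assigned_class=cls,
                weights={f: w for f in features},
            )
    return AnnotationRecord(
        sequence=read.sequence,
        multiplicity=read.multiplicity,
        assigned_class=OTHERS,
        weights={},
    )


# --------------------------------------------------------------------------
# Count matrix
# --------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Features x samples counts with size factors and sample metadata.

    ``normalized = raw / size_factors`` column-wise. ``others`` holds the
    per-sample multiplicity of unannotated reads; ``class_composition`` the
    per-sample fraction of read multiplicity per annotation class.
    """

    raw: pd.DataFrame
    size_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None
    others: pd.Series | None = None
    class_composition: pd.DataFrame | None = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw.columns)


def build_count_matrix(
    annotations: dict[str, list[AnnotationRecord]], bundle: ReferenceBundle
) -> CountMatrix:
    """Aggregate per-sample annotation records into a raw count matrix.

    raw[i, j] = sum over reads of multiplicity x weight for feature i in
    sample j. Also emits the per-sample class composition (fractions of total
    collapsed multiplicity, including "others").
    """
    sample_ids = list(annotations)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    feature_ids = bundle.feature_ids
    raw = pd.DataFrame(0.0, index=feature_ids, columns=sample_ids)
    others = pd.Series(0.0, index=sample_ids)
    comp = pd.DataFrame(0.0, index=list(RNA_CLASSES) + [OTHERS], columns=sample_ids)
    for sample, records in annotations.items():
        for rec in records:
            comp.loc[rec.assigned_class, sample] += rec.multiplicity
            if rec.assigned_class == OTHERS:
                others[sample] += rec.multiplicity
                continue
            for feat, w in rec.weights.items():
                raw.loc[feat, sample] += rec.multiplicity * w
    totals = comp.sum(axis=0)
    comp = comp.div(totals.where(totals > 0, 1.0), axis=1)
    return CountMatrix(raw=raw, others=others, class_composition=comp)


def compute_size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over features i of raw[i, j] / geomean_i, where geomean_i is
    the geometric mean of feature i across samples, restricted to features
    positive in every sample. Factors are rescaled to geometric mean 1 (they
    are defined only up to a constant); this makes the estimator exactly
    equivariant to per-sample scaling and a fixed point under renormalization.
    """
    values = raw.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError("size factors undefined: no feature nonzero in all samples")
    sub = values[positive]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    log_factors = np.median(ratios, axis=0)
    factors = np.exp(log_factors - np.mean(log_factors))
    return pd.Series(factors, index=raw.columns, name="size_factor")


def normalize_counts(raw: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """normalized[i, j] = raw[i, j] / s_j."""
    sf = size_factors.reindex(raw.columns)
    if (sf <= 0).any() or sf.isna().any():
        raise ValueError("size factors must be positive for every sample")
    return raw.div(sf, axis=1)


def filter_expressed(
    normalized: pd.DataFrame, min_mean: float = 1.0, min_frequency: float = 0.25
) -> pd.DataFrame:
    """Keep features with mean normalized count > min_mean and detection
    frequency strictly above min_frequency (both strict, per the call rule)."""
    mean_ok = normalized.mean(axis=1) > min_mean
    freq_ok = (normalized > 0).mean(axis=1) > min_frequency
    return normalized.loc[mean_ok & freq_ok]


# --------------------------------------------------------------------------
# End-to-end per-sample quantification
# --------------------------------------------------------------------------


def quantify_samples(
    sample_reads: dict[str, list[str]],
    bundle: ReferenceBundle,
    adapter: str | None,
    min_length: int = MIN_READ_LENGTH,
    max_mismatches: int = 0,
    require_adapter: bool = True,
) -> tuple[CountMatrix, dict[str, TrimLog]]:
    """FASTQ-level sequences per sample -> raw+normalized CountMatrix."""
    matcher = ReadMatcher(bundle, max_mismatches)
    annotations: dict[str, list[AnnotationRecord]] = {}
    logs: dict[str, TrimLog] = {}
    for sample, reads in sample_reads.items():
        trimmed, log = trim_and_filter(
            reads, adapter, min_length=min_length, require_adapter=require_adapter
        )
        logs[sample] = log
        collapsed = collapse_reads(trimmed)
        annotations[sample] = [
            classify_read(cr, matcher.match_read(cr)) for cr in collapsed
        ]
    cm = build_count_matrix(annotations, bundle)
    cm.size_factors = compute_size_factors(cm.raw)
    cm.normalized = normalize_counts(cm.raw, cm.size_factors)
    return cm, logs


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Read sequences from a FASTQ file (plain text, Phred+33)."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
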