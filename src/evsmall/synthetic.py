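"""Synthetic cohort generator.

Emulates the statistical structure of a three-group (healthy / iRBD / PD)
plasma-EV small-RNA study so every analysis stage can be exercised against a
known ground truth: reference bundles with mature miRNAs anchored in
precursors, FASTQ reads with templated 3' isomiR variation and class-specific
length ranges, negative-binomial count matrices with planted fold changes and
monotone trajectories, and an iRBD phenoconversion cohort with planted
per-miRNA hazard effects.

Everything is deterministic given the config seed. References and reads use
the DNA alphabet (T, not U), matching FASTQ convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import RNA_CLASSES, ReferenceBundle, SncRnaReference

#: Read-length ranges (nt, inclusive) emulated per class. miRNA reads are
#: governed by the anchored isomiR rule instead of a range. The non-miRNA
#: per-class read fractions of a real library are not pinned down by the
#: study; these spans follow the reported class length structure
#: (ysRNA 25-33, tsRNA 30-33, rsRNA 17-20).
READ_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "ysRNA": (25, 33),
    "tsRNA": (30, 33),
    "rsRNA": (17, 20),
    "snRNA": (20, 30),
    "snoRNA": (20, 30),
    "lncRNA": (20, 32),
    "mRNA": (20, 32),
}

#: Reference-sequence length ranges per non-miRNA class (reads are substrings).
REFERENCE_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "ysRNA": (80, 112),
    "tsRNA": (70, 90),
    "rsRNA": (120, 160),
    "snRNA": (100, 150),
    "snoRNA": (60, 120),
    "lncRNA": (200, 400),
    "mRNA": (200, 500),
}

#: Default distribution of the 3' isomiR shift delta in {-3..+3}; mass
#: concentrated on the canonical 3' end with symmetric +-1/2/3 tails.
DEFAULT_DELTA_PROBS: dict[int, float] = {
    -3: 0.02,
    -2: 0.05,
    -1: 0.13,
    0: 0.60,
    1: 0.13,
    2: 0.05,
    3: 0.02,
}

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

MIN_FOLD_CHANGE = 1.4

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study-condition parameters for all generators.

    Group sizes default to the 60/56/53 healthy/iRBD/PD cohort; planted
    effects default to 2-fold (log2fc = 1), comfortably above the 1.4-fold
    differential-expression floor.
    """

    seed: int = 0
    n_healthy: int = 60
    n_irbd: int = 56
    n_pd: int = 53
    n_mirna: int = 500
    n_other_per_class: int = 20
    frac_de: float = 0.2
    planted_log2fc: float = 1.0
    nb_dispersion: float = 0.15
    depth_mean: float = 2e4
    conversion_hazard_ratio: float = 3.0
    n_conversion_features: int = 4
    followup_horizon: float = 3.3
    mature_len_range: tuple[int, int] = (18, 23)
    precursor_len_range: tuple[int, int] = (60, 90)
    n_decoys: int = 0
    pd_irbd_overlap: int = 18  # PD patients also presenting with iRBD

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_irbd", "n_pd", "n_mirna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.planted_log2fc < math.log2(MIN_FOLD_CHANGE) - 1e-12:
            raise ValueError(
                f"planted_log2fc must be >= log2({MIN_FOLD_CHANGE}) "
                "(the differential-expression fold-change floor)"
            )
        if self.mature_len_range[1] + 3 > self.precursor_len_range[0]:
            raise ValueError(
                "precursor length must allow the mature sequence plus a 3 nt "
                "downstream margin (mature_len_range max + 3 <= precursor min)"
            )

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"healthy": self.n_healthy, "iRBD": self.n_irbd, "PD": self.n_pd}


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    de_features maps a contrast "A:B" to {feature_id: sign} for features whose
    planted A/B group-mean ratio exceeds the 1.4-fold floor. patterns maps
    every miRNA to one of {up, down, other, flat} over the healthy->iRBD->PD
    hierarchy. conversion_features lists miRNAs with planted hazard effects.
    """

    de_features: dict[str, dict[str, int]] = field(default_factory=dict)
    patterns: dict[str, str] = field(default_factory=dict)
    conversion_features: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# Reference bundle
# --------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_reference_bundle(config: SyntheticConfig) -> ReferenceBundle:
    """Random reference bundle: anchored miRNA precursors + other classes.

    Each miRNA gets a random precursor (default 60-90 nt) containing its
    mature sequence (default 18-23 nt) at a random offset with at least 3 nt
    of precursor downstream of the mature 3' end (so every templated +3
    extension exists). With ``n_decoys > 0``, the first ``n_decoys`` miRNA
    mature sequences are embedded into ysRNA references to create
    cross-class ambiguity for annotation-priority testing.
    """
    rng = np.random.default_rng(config.seed)
    bundle = ReferenceBundle()
    mat_lo, mat_hi = config.mature_len_range
    pre_lo, pre_hi = config.precursor_len_range
    for i in range(config.n_mirna):
        mature_len = int(rng.integers(mat_lo, mat_hi + 1))
        pre_len = int(rng.integers(pre_lo, pre_hi + 1))
        start = int(rng.integers(0, pre_len - mature_len - 3 + 1))
        precursor = _random_seq(rng, pre_len)
        bundle.add(
            SncRnaReference(
                feature_id=f"miR-{i + 1:04d}",
                rna_class="miRNA",
                sequence=precursor[start : start + mature_len],
                precursor_sequence=precursor,
                mature_start=start,
                mature_end=start + mature_len,
            )
        )
    decoy_matures = [
        bundle[f"miR-{i + 1:04d}"].sequence
        for i in range(min(config.n_decoys, config.n_mirna))
    ]
    for cls in RNA_CLASSES[1:]:
        lo, hi = REFERENCE_LENGTH_RANGES[cls]
        for i in range(config.n_other_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length)
            if cls == "ysRNA" and i < len(decoy_matures):
                mat = decoy_matures[i]
                pos = int(rng.integers(0, length - len(mat) + 1))
                seq = seq[:pos] + mat + seq[pos + len(mat) :]
            bundle.add(
                SncRnaReference(feature_id=f"{cls}-{i + 1:03d}", rna_class=cls, sequence=seq)
            )
    return bundle


# --------------------------------------------------------------------------
# Reads
# --------------------------------------------------------------------------


def _mirna_read(
    rng: np.random.Generator, ref: SncRnaReference, delta_probs: dict[int, float]
) -> str:
    """Draw one templated isomiR read; delta constrained so the read stays
    >= 17 nt (otherwise the length filter would break exact round-trips)."""
    mature_len = ref.mature_end - ref.mature_start
    deltas = [d for d in delta_probs if mature_len + d >= 17]
    probs = np.array([delta_probs[d] for d in deltas], dtype=float)
    probs /= probs.sum()
    delta = int(rng.choice(deltas, p=probs))
    return ref.precursor_sequence[ref.mature_start : ref.mature_end + delta]


def simulate_reads(
    bundle: ReferenceBundle,
    config: SyntheticConfig,
    sample_profile: dict[str, int],
    delta_probs: dict[int, float] | None = None,
    contaminant_fraction: float = 0.0,
    adapter: str = DEFAULT_ADAPTER,
    adapter_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Simulate one sample's reads as (read_id, sequence) pairs.

    Each feature in ``sample_profile`` emits exactly that many reads. miRNA
    reads start at the mature 5' site and end at mature 3' + delta with
    templated extensions; other classes emit random substrings in their class
    length range. ``contaminant_fraction`` of extra reads are appended:
    adapter dimers, sub-17-nt inserts, and (when the bundle has decoys)
    reads matching two classes at once. Contaminants are labeled in the read
    id so filters can be asserted. The 3' adapter is appended to
    ``adapter_fraction`` of reads.
    """
    unknown = set(sample_profile) - set(bundle.feature_ids)
    if unknown:
        raise ValueError(f"profile keys not in bundle: {sorted(unknown)[:5]}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if delta_probs is None:
        delta_probs = DEFAULT_DELTA_PROBS
    reads: list[tuple[str, str]] = []
    serial = 0
    for feature_id, count in sample_profile.items():
        ref = bundle[feature_id]
        for _ in range(int(count)):
            if ref.rna_class == "miRNA":
                seq = _mirna_read(rng, ref, delta_probs)
            else:
                lo, hi = READ_LENGTH_RANGES[ref.rna_class]
                hi = min(hi, len(ref.sequence))
                length = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, len(ref.sequence) - length + 1))
                seq = ref.sequence[start : start + length]
            serial += 1
            reads.append((f"read{serial:07d}:{feature_id}", seq))
    n_contam = int(round(contaminant_fraction * len(reads)))
    decoy_ids = [f for f in bundle.feature_ids if f.startswith("ysRNA")][: config.n_decoys]
    kinds = ["adapter_dimer", "short"] + (["ambiguous"] if decoy_ids else [])
    for i in range(n_contam):
        kind = kinds[i % len(kinds)]
        if kind == "adapter_dimer":
            seq = ""
        elif kind == "short":
            seq = _random_seq(rng, int(rng.integers(8, 17)))
        else:
            # valid miRNA read whose mature is embedded in a ysRNA decoy
            mi = int(rng.integers(0, min(config.n_decoys, config.n_mirna)))
            seq = bundle[f"miR-{mi + 1:04d}"].sequence
        serial += 1
        reads.append((f"read{serial:07d}:contam:{kind}", seq))
    out = []
    for rid, seq in reads:
        if rng.random() < adapter_fraction:
            seq = seq + adapter
        out.append((rid, seq))
    return out


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ (constant quality 'I')."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# --------------------------------------------------------------------------
# Count matrix
# --------------------------------------------------------------------------

GROUPS = ("healthy", "iRBD", "PD")

#: Table-1 sex composition (male fraction) per group; the PD group is
#: female-skewed, so sex is a real confounder for PD contrasts.
SEX_MALE_FRACTION = {"healthy": 35 / 60, "iRBD": 34 / 56, "PD": 25 / 53}

_NONMONO_SHAPES = ((1.0, 1.0, 0.0), (0.0, 1.0, 0.0), (1.0, 0.0, 1.0), (0.0, 0.0, 1.0))


def _plant_patterns(
    rng: np.random.Generator, features: list[str], frac_de: float, log2fc: float
) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    """Assign each feature a trajectory pattern and group multipliers."""
    f = 2.0 ** log2fc
    n_de = int(round(frac_de * len(features)))
    de_idx = rng.choice(len(features), size=n_de, replace=False)
    patterns = {feat: "flat" for feat in features}
    multipliers = {feat: np.ones(3) for feat in features}
    for j, idx in enumerate(de_idx):
        feat = features[idx]
        kind = ("up", "down", "other")[j % 3]
        patterns[feat] = kind
        if kind == "up":
            multipliers[feat] = np.array([1.0, math.sqrt(f), f])
        elif kind == "down":
            multipliers[feat] = np.array([f, math.sqrt(f), 1.0])
        else:
            shape = _NONMONO_SHAPES[int(rng.integers(0, len(_NONMONO_SHAPES)))]
            multipliers[feat] = f ** np.array(shape)
    return patterns, multipliers


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mu + dispersion * mu^2 via gamma-Poisson mixing."""
    if dispersion < 1e-8:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_count_matrix(config: SyntheticConfig):
    """Three-group miRNA count matrix with planted effects.

    Returns (CountMatrix with raw/size-factor/normalized counts and metadata,
    GroundTruth). Counts are negative-binomial around
    baseline x library-size x group-effect x mild sex/batch effects; metadata
    carries group, sex (PD female-skewed), age, batch, and a PD-iRBD subgroup
    flag mirroring the 18-of-53 overlap.
    """
    from .quant import CountMatrix, compute_size_factors, normalize_counts

    rng = np.random.default_rng(config.seed)
    features = [f"miR-{i + 1:04d}" for i in range(config.n_mirna)]
    patterns, multipliers = _plant_patterns(
        rng, features, config.frac_de, config.planted_log2fc
    )

    # sample metadata
    rows = []
    for group in GROUPS:
        n = config.group_sizes[group]
        n_male = int(round(SEX_MALE_FRACTION[group] * n))
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sexes)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:03d}",
                    "group": group,
                    "sex": sexes[i],
                    "age": float(np.round(rng.normal(63.5, 8.0), 1)),
                    "batch": f"b{int(rng.integers(1, 3))}",
                }
            )
    metadata = pd.DataFrame(rows).set_index("sample_id")
    metadata["pd_irbd"] = False
    pd_ids = metadata.index[metadata["group"] == "PD"]
    overlap = rng.choice(
        pd_ids, size=min(config.pd_irbd_overlap, len(pd_ids)), replace=False
    )
    metadata.loc[overlap, "pd_irbd"] = True

    # expected means
    baseline = rng.lognormal(mean=np.log(30.0), sigma=1.6, size=config.n_mirna)
    baseline *= config.depth_mean / baseline.sum()
    lib_size = rng.lognormal(mean=0.0, sigma=0.25, size=len(metadata))
    # mild (<=1.2-fold) sex and batch effects on random 10% feature subsets
    sex_feats = rng.random(config.n_mirna) < 0.1
    batch_feats = rng.random(config.n_mirna) < 0.1
    sex_mult = np.where(sex_feats, 1.15, 1.0)
    batch_mult = np.where(batch_feats, 1.15, 1.0)

    group_idx = {g: k for k, g in enumerate(GROUPS)}
    mult_matrix = np.stack([multipliers[f] for f in features])  # features x 3
    mean = np.empty((config.n_mirna, len(metadata)))
    for j, (sid, meta) in enumerate(metadata.iterrows()):
        g = group_idx[meta["group"]]
        mu = baseline * mult_matrix[:, g] * lib_size[j]
        if meta["sex"] == "M":
            mu = mu * sex_mult
        if meta["batch"] == "b2":
            mu = mu * batch_mult
        mean[:, j] = mu
    counts = _nb_sample(rng, mean, config.nb_dispersion).astype(float)
    raw = pd.DataFrame(counts, index=features, columns=metadata.index)

    cm = CountMatrix(raw=raw, metadata=metadata)
    cm.size_factors = compute_size_factors(raw)
    cm.normalized = normalize_counts(raw, cm.size_factors)

    truth = GroundTruth(patterns=patterns)
    contrasts = {"PD:healthy": (2, 0), "iRBD:healthy": (1, 0), "PD:iRBD": (2, 1)}
    for name, (a, b) in contrasts.items():
        calls: dict[str, int] = {}
        for i, feat in enumerate(features):
            ratio = mult_matrix[i, a] / mult_matrix[i, b]
            if ratio > MIN_FOLD_CHANGE:
                calls[feat] = 1
            elif 1.0 / ratio > MIN_FOLD_CHANGE:
                calls[feat] = -1
        truth.de_features[name] = calls
    return cm, truth


# --------------------------------------------------------------------------
# Conversion survival cohort
# --------------------------------------------------------------------------


def simulate_conversion_cohort(
    config: SyntheticConfig,
    baseline_hazard: float = 0.045,
    n_features: int | None = None,
):
    """iRBD phenoconversion cohort with planted per-miRNA hazard effects.

    Event times are exponential with hazard
    ``baseline_hazard * exp(beta * z_miRNA + 0.02*(age-64) + 0.1*sex)`` for
    the planted conversion features (beta = log hazard ratio per SD),
    administratively censored at the follow-up horizon (default 3.3 years).
    Returns (DataFrame with time/event/age/sex + feature columns, GroundTruth).
    The default baseline hazard yields roughly 8 converters among 56 patients
    over 3.3 years, the scale of the observed cohort.
    """
    if config.n_irbd <= 0:
        raise ValueError("n_irbd must be > 0")
    rng = np.random.default_rng(config.seed)
    n = config.n_irbd
    k = n_features if n_features is not None else max(config.n_conversion_features, 10)
    feat_names = [f"miR-{i + 1:04d}" for i in range(k)]
    levels = rng.normal(size=(n, k))  # standardized expression
    beta = math.log(config.conversion_hazard_ratio)
    conv_idx = list(range(min(config.n_conversion_features, k)))
    age = rng.normal(64.0, 7.0, size=n)
    sex = (rng.random(n) < SEX_MALE_FRACTION["iRBD"]).astype(int)  # 1 = male
    linpred = levels[:, conv_idx].sum(axis=1) * beta + 0.02 * (age - 64.0) + 0.1 * sex
    hazard = baseline_hazard * np.exp(linpred)
    event_time = rng.exponential(1.0 / np.maximum(hazard, 1e-300))
    horizon = config.followup_horizon
    observed = np.minimum(event_time, horizon)
    event = (event_time <= horizon).astype(int)
    df = pd.DataFrame(
        {
            "sample_id": [f"iRBD_{i + 1:03d}" for i in range(n)],
            "time": observed,
            "event": event,
            "age": np.round(age, 1),
            "sex": np.where(sex == 1, "M", "F"),
        }
    ).set_index("sample_id")
    for j, name in enumerate(feat_names):
        df[name] = levels[:, j]
    truth = GroundTruth(conversion_features=[feat_names[i] for i in conv_idx])
    return df, truth
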