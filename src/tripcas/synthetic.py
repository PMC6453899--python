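"""Seed-controlled generators for reporter libraries, Cas9 amplicon reads,
genomic feature tracks and hairpin DSB-end reads.

The generators emulate a multiplexed Cas9 mutation-profiling study on
barcoded reporters integrated genome-wide: each integrated reporter (IR)
carries a unique barcode, a promoter with a 5-nt promoter index, and a
target region harboring three guide target sites.  Reads follow the layout
in :mod:`tripcas.readcall` (UID + anchor + barcode + anchor + promoter
index + target region).

The generative model per molecule: the IR mutates with probability
``p_ir * g_guide`` (``p_ir`` ~ Beta(a, b) per locus, shared across assays;
``g_guide`` a guide-efficiency multiplier).  Mutated molecules draw an
outcome from a mixture of knock-in (ssODN assays only), complex
(deletion+insertion), insertion and deletion.  1-bp insertions follow the
blunt/staggered dichotomy: with probability ``f_staggered`` the ntDNA
nucleotide 4 is duplicated at junction 4|5 (template-dependent fill-in of a
1-nt 5' overhang), otherwise a uniformly random base is added at the blunt
junction 3|4.  Deletion sizes are truncated-geometric with an optional
microhomology spike deleting one unit of a tandem triplet repeat.

All randomness flows from one root seed through per-IR child streams, so
adding an IR never perturbs the reads of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .readcall import DEFAULT_LAYOUT, GuideTarget, ReadLayout, revcomp
from .end_structures import EndStructure, expected_hairpin_read
from .context import FeatureTrack

__all__ = [
    "GenerationError",
    "SimulationConfig",
    "ReporterConstruct",
    "SsOdn",
    "DEFAULT_GUIDES",
    "SSODN_INSERT",
    "build_ssodn",
    "generate_reporter_library",
    "simulate_cas9_reads",
    "simulate_insertion_events",
    "simulate_factorial_frequencies",
    "simulate_feature_tracks",
    "simulate_hcodes_reads",
    "library_table",
    "write_fastq",
]

BASES = "ACGT"


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its contract."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model; defaults encode the study conditions.

    ``f_staggered`` maps guide name -> fraction of cleavage events that
    produce a 1-nt 5' overhang (the remainder are blunt); scalar values
    apply to every guide.  ``guide_efficiency`` multiplies the per-IR
    mutation propensity.  Coverage is negative-binomial with the given mean
    and dispersion (shape); ``seq_error_rate`` injects i.i.d. substitution
    errors only, so sequencing noise never fabricates indel calls.
    """

    seed: int = 0
    n_irs: int = 36
    promoters: tuple = (("PGK", 1.0),)
    propensity_beta: tuple = (2.0, 2.0)
    guide_efficiency: object = None  # dict name->mult, scalar, or None (defaults)
    f_staggered: object = None  # dict name->f, scalar, or None (defaults)
    deletion_geom_p: float = 0.15
    deletion_max: int = 30
    microhomology: tuple | None = None  # (triplet, probability)
    insertion_prob: float = 0.15
    ins1_prob: float = 0.9
    knockin_prob: float = 0.05
    complex_prob: float = 0.05
    coverage_mean: float = 60.0
    coverage_dispersion: float = 5.0
    seq_error_rate: float = 0.001
    uid_dup_mean: float = 0.3
    bisulfite_failure_rate: float = 0.0
    barcode_length: int = 16

    def __post_init__(self) -> None:
        probs = {
            "deletion_geom_p": self.deletion_geom_p,
            "insertion_prob": self.insertion_prob,
            "ins1_prob": self.ins1_prob,
            "knockin_prob": self.knockin_prob,
            "complex_prob": self.complex_prob,
            "seq_error_rate": self.seq_error_rate,
            "bisulfite_failure_rate": self.bisulfite_failure_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if isinstance(self.f_staggered, (int, float)) and not 0.0 <= self.f_staggered <= 1.0:
            raise ValueError("f_staggered must be in [0, 1]")
        if isinstance(self.f_staggered, dict):
            for k, v in self.f_staggered.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"f_staggered[{k}] must be in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage mean must be positive")
        if self.microhomology is not None:
            triplet, p = self.microhomology
            if len(triplet) != 3 or not 0.0 <= p <= 1.0:
                raise ValueError("microhomology must be (triplet, probability)")
        if self.barcode_length not in (16, 18):
            raise ValueError("barcode length must be 16 or 18")
        weights = [w for _, w in self.promoters]
        if not weights or any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValueError("promoter weights must be non-negative and sum > 0")

    def staggered_fraction(self, guide: str) -> float:
        if self.f_staggered is None:
            return DEFAULT_F_STAGGERED.get(guide, 0.6)
        if isinstance(self.f_staggered, dict):
            return self.f_staggered[guide]
        return float(self.f_staggered)

    def efficiency(self, guide: str) -> float:
        if self.guide_efficiency is None:
            return DEFAULT_GUIDE_EFFICIENCY.get(guide, 1.0)
        if isinstance(self.guide_efficiency, dict):
            return self.guide_efficiency[guide]
        return float(self.guide_efficiency)

    # flat key=value round trip -------------------------------------------

    def to_flat(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name}={getattr(self, f.name)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_flat(cls, text: str) -> "SimulationConfig":
        import ast

        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = ast.literal_eval(value.strip())
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Default assay design
# ---------------------------------------------------------------------------

# Three guides mirroring the study design: two GC-rich guides with template
# base (ntDNA position 4) G — guide 1 ending in a CGG.CGG tandem repeat so
# microhomology can delete one CGG unit at positions 1-3 or 4-6 upstream of
# the PAM — and one AT-rich guide with template base T.
DEFAULT_GUIDES = (
    GuideTarget(protospacer="GCTAGCCGCAGCGACGGCGG", pam="TGG", name="sgG1"),
    GuideTarget(protospacer="CACCGGCTGCAGCCGGGCAC", pam="AGG", name="sgG2"),
    GuideTarget(protospacer="ATGACTTCAATGACGATCAA", pam="TGG", name="sgG3"),
)

# staggered fractions back-computed from dominant 1-bp insertion shares via
# share = f + (1 - f)/4
DEFAULT_F_STAGGERED = {"sgG1": 0.52, "sgG2": 0.65, "sgG3": 0.97}
DEFAULT_GUIDE_EFFICIENCY = {"sgG1": 1.0, "sgG2": 1.0, "sgG3": 1.3}

_FLANKS = (
    "ACGATCCTGATAGCT",
    "TCAGGTCATGAACTG",
    "GATCCAATGTCCAGT",
    "CATGGAGTACCTTGAGATCCGTACAATGCA",
)

TARGET_REGION = (
    _FLANKS[0]
    + DEFAULT_GUIDES[0].ntdna
    + _FLANKS[1]
    + DEFAULT_GUIDES[1].ntdna
    + _FLANKS[2]
    + DEFAULT_GUIDES[2].ntdna
    + _FLANKS[3]
)

PROMOTER_WEIGHTS_POOL = (
    ("CMV", 2.0), ("cMyc", 2.0), ("Hoxb1", 4.0), ("Nanog", 2.0),
    ("Oct4", 2.0), ("p53", 2.0), ("PGK", 1.0),
)

_PROMOTER_INDICES = {
    "CMV": "ACTGA", "cMyc": "CGATC", "Hoxb1": "GTCAG", "Nanog": "TAGCT",
    "Oct4": "AGTCA", "p53": "CATGC", "PGK": "GACTG",
}

_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 6))
_CHROM_SLOTS = 2500  # loci on a 4 kb grid per 10 Mb chromosome
_SLOT_SPACING = 4000

SSODN_INSERT = "GGATCCGAATTCAAGCTTGCA"  # 21-nt knock-in payload


def promoter_index(label: str) -> str:
    """Stable 5-nt index per promoter label."""
    if label in _PROMOTER_INDICES:
        return _PROMOTER_INDICES[label]
    h = zlib.crc32(label.encode())
    return "".join(BASES[(h >> (2 * k)) & 3] for k in range(5))


@dataclass(frozen=True)
class SsOdn:
    """Single-stranded oligo repair template: insert plus homology arms."""

    template: str
    insert: str
    arm_left: int
    arm_right: int

    def __post_init__(self) -> None:
        if len(self.template) != self.arm_left + len(self.insert) + self.arm_right:
            raise ValueError("template length must equal arms + insert")


def build_ssodn(target_region: str, cut_bond: int, insert: str = SSODN_INSERT,
                arm_left: int = 58, arm_right: int = 62) -> SsOdn:
    if cut_bond < arm_left or len(target_region) - cut_bond < arm_right:
        raise GenerationError("target region too short for ssODN homology arms")
    template = (
        target_region[cut_bond - arm_left : cut_bond]
        + insert
        + target_region[cut_bond : cut_bond + arm_right]
    )
    return SsOdn(template=template, insert=insert, arm_left=arm_left, arm_right=arm_right)


@dataclass(frozen=True)
class ReporterConstruct:
    """One barcoded reporter integration."""

    barcode: str
    promoter: str
    promoter_index: str
    locus: tuple  # (chromosome, 0-based position, strand)
    target_region: str
    propensity: float  # baseline mutation probability of this locus
    ssodn: SsOdn | None = None


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def generate_reporter_library(config: SimulationConfig) -> list:
    """Generate ``config.n_irs`` reporters with unique barcodes.

    Promoters are drawn by weight, loci without collision on a spaced grid
    (so feature-track windows around neighboring loci never overlap), and
    per-locus propensities from Beta(a, b).  Deterministic given the seed.
    """
    if config.n_irs < 1:
        raise GenerationError("n_irs must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x11B]))
    labels = [p for p, _ in config.promoters]
    weights = np.array([w for _, w in config.promoters], dtype=float)
    weights /= weights.sum()
    total_slots = len(_CHROMOSOMES) * _CHROM_SLOTS
    if config.n_irs > total_slots:
        raise GenerationError("more IRs than available genomic slots")
    slots = rng.choice(total_slots, size=config.n_irs, replace=False)
    a, b = config.propensity_beta
    propensities = rng.beta(a, b, size=config.n_irs)
    barcodes: set = set()
    library = []
    for i in range(config.n_irs):
        for attempt in range(50):
            bc = _random_seq(rng, config.barcode_length)
            if bc not in barcodes:
                break
        else:
            raise GenerationError("barcode space exhausted after bounded retries")
        barcodes.add(bc)
        prom = labels[int(rng.choice(len(labels), p=weights))]
        slot = int(slots[i])
        chrom = _CHROMOSOMES[slot // _CHROM_SLOTS]
        pos = (slot % _CHROM_SLOTS) * _SLOT_SPACING + int(rng.integers(0, 500)) + 2000
        strand = "+" if rng.random() < 0.5 else "-"
        library.append(
            ReporterConstruct(
                barcode=bc,
                promoter=prom,
                promoter_index=promoter_index(prom),
                locus=(chrom, pos, strand),
                target_region=TARGET_REGION,
                propensity=float(propensities[i]),
            )
        )
    return library


def library_table(library) -> pd.DataFrame:
    """Tabular TSV-ready view of a reporter library."""
    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in library],
            "promoter": [c.promoter for c in library],
            "promoter_index": [c.promoter_index for c in library],
            "chromosome": [c.locus[0] for c in library],
            "position": [c.locus[1] for c in library],
            "strand": [c.locus[2] for c in library],
            "propensity": [c.propensity for c in library],
        }
    )


# ---------------------------------------------------------------------------
# Cas9 amplicon reads
# ---------------------------------------------------------------------------


def _draw_deletion(rng, frame, config):
    """Deletion interval (start, size) in reference coordinates."""
    ref = frame.ntref
    cut = frame.cut_bond
    if config.microhomology is not None:
        triplet, p_spike = config.microhomology
        tandem = ref.find(triplet + triplet, max(0, frame.pam_index - 12), frame.pam_index + 3)
        if tandem >= 0 and rng.random() < p_spike:
            return tandem + 3, 3  # delete the PAM-proximal repeat unit
    size = 1 + min(int(rng.geometric(config.deletion_geom_p)) - 1, config.deletion_max - 1)
    offset = int(rng.integers(0, size + 1))
    start = min(max(cut - offset, 1), len(ref) - size - 1)
    return start, size


def _mutate_target(rng, frame, config, guide, with_ssodn, ssodn):
    """Draw one mutated target sequence; returns (sequence, outcome, knockin, detail)."""
    ref = frame.ntref
    cut = frame.cut_bond
    if with_ssodn and ssodn is not None and rng.random() < config.knockin_prob:
        seq = ref[:cut] + ssodn.insert + ref[cut:]
        return seq, "insertion", True, f"knockin:{len(ssodn.insert)}"
    if rng.random() < config.complex_prob:
        size = int(rng.integers(2, 6))
        dstart = max(cut - size - 4, 1)
        ins_bond = min(cut + 4, len(ref) - 1)
        left, right = ref[ins_bond - 1], ref[ins_bond]
        choices = [b for b in BASES if b != left and b != right]
        ins = choices[int(rng.integers(0, len(choices)))]
        seq = ref[:dstart] + ref[dstart + size : ins_bond] + ins + ref[ins_bond:]
        return seq, "complex", False, f"del:{size}+ins:1"
    if rng.random() < config.insertion_prob:
        if rng.random() < config.ins1_prob:
            if rng.random() < config.staggered_fraction(guide.name):
                base = guide.nucleotide4
                bond = frame.junction_to_bond(4)
            else:
                base = BASES[int(rng.integers(0, 4))]
                bond = frame.junction_to_bond(3)
            seq = ref[:bond] + base + ref[bond:]
            return seq, "insertion", False, f"ins1:{base}"
        size = int(rng.integers(2, 7))
        ins = _random_seq(rng, size)
        bond = frame.junction_to_bond(3)
        seq = ref[:bond] + ins + ref[bond:]
        return seq, "insertion", False, f"ins:{size}"
    start, size = _draw_deletion(rng, frame, config)
    seq = ref[:start] + ref[start + size :]
    return seq, "deletion", False, f"del:{size}@{start}"


def _inject_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_err, replace=False):
        current = chars[pos]
        alternatives = [b for b in BASES if b != current]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _to_nt_orientation(seq: str, guide: GuideTarget) -> str:
    return seq if guide.orientation == "sense" else revcomp(seq)


def simulate_cas9_reads(
    library,
    guide: GuideTarget,
    config: SimulationConfig,
    with_ssodn: bool = False,
    layout: ReadLayout = DEFAULT_LAYOUT,
    assay: str | None = None,
):
    """Simulate one Cas9 assay over a reporter library.

    Returns ``(reads, truth)``: ``reads`` is a list of (name, sequence)
    pairs and ``truth`` a per-read DataFrame of the generating outcomes
    (recorded before sequencing-error injection).  Raises
    :class:`GenerationError` if the guide is absent from any construct.
    """
    assay = assay or f"{guide.name}{'+ssODN' if with_ssodn else '-ssODN'}"
    frames = {}
    ssodns = {}
    for c in library:
        try:
            frames[c.barcode] = guide.frame(c.target_region)
        except ValueError as exc:
            raise GenerationError(f"guide absent from construct {c.barcode}: {exc}")
        if with_ssodn:
            ssodns[c.barcode] = c.ssodn or build_ssodn(
                _to_nt_orientation(c.target_region, guide), frames[c.barcode].cut_bond
            )
    root = np.random.SeedSequence(
        [config.seed, zlib.crc32(assay.encode()) & 0x7FFFFFFF, 0xCA5]
    )
    streams = root.spawn(len(library))
    reads = []
    truth_rows = []
    for c, stream in zip(library, streams):
        rng = np.random.default_rng(stream)
        frame = frames[c.barcode]
        p_mut = min(c.propensity * config.efficiency(guide.name), 0.98)
        shape = config.coverage_dispersion
        coverage = max(
            1, int(rng.negative_binomial(shape, shape / (shape + config.coverage_mean)))
        )
        for mol in range(coverage):
            uid = _random_seq(rng, layout.uid_length)
            if rng.random() >= p_mut:
                nt_target, outcome, knockin, detail = frame.ntref, "wild_type", False, ""
            else:
                nt_target, outcome, knockin, detail = _mutate_target(
                    rng, frame, config, guide, with_ssodn, ssodns.get(c.barcode)
                )
            target = nt_target if guide.orientation == "sense" else revcomp(nt_target)
            clean = (
                uid + layout.anchor1 + c.barcode + layout.anchor2
                + c.promoter_index + target
            )
            n_reads = 1 + rng.poisson(config.uid_dup_mean)
            for r in range(n_reads):
                name = f"{assay}:{c.barcode}:{mol}:{r}"
                reads.append((name, _inject_errors(rng, clean, config.seq_error_rate)))
                truth_rows.append(
                    {
                        "assay": assay, "read": name, "barcode": c.barcode,
                        "uid": uid, "outcome": outcome, "knockin": knockin,
                        "detail": detail,
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["assay", "read", "barcode", "uid", "outcome", "knockin", "detail"],
    )
    return reads, truth


def write_fastq(path, reads) -> None:
    """Write (name, sequence) pairs as plain 4-line FASTQ."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(seq), id=name, description="",
            letter_annotations={"phred_quality": [40] * len(seq)},
        )
        for name, seq in reads
    ]
    seqio_write(records, str(path), "fastq")


def read_fastq(path):
    """Read plain/gzip FASTQ into (name, sequence) pairs."""
    import gzip

    from Bio.SeqIO import parse as seqio_parse

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        return [(rec.id, str(rec.seq)) for rec in seqio_parse(fh, "fastq")]


# ---------------------------------------------------------------------------
# Direct insertion-event sampling (for the cleavage-model machinery)
# ---------------------------------------------------------------------------


def simulate_insertion_events(
    guide: GuideTarget,
    n: int,
    f_staggered: float,
    rng: np.random.Generator,
):
    """Sample n 1-bp insertion events under the blunt/staggered mixture and
    report each at its caller-convention junction (the 3'-most junction of
    its ambiguity window, i.e. toward the PAM), as a deterministic variant
    caller would.

    Returns a list of (base, reported_junction) pairs.
    """
    from .insertion_models import window_for

    ntref = guide.ntdna
    pam_index = 20
    events = []
    for _ in range(n):
        if rng.random() < f_staggered:
            base, true_j = guide.nucleotide4, 4
        else:
            base, true_j = BASES[int(rng.integers(0, 4))], 3
        w = window_for(ntref, pam_index, base, true_j)
        reported = min(w.junctions) if w is not None else true_j
        events.append((base, reported))
    return events


# ---------------------------------------------------------------------------
# Factorial mutation-frequency generator (effect-size recovery)
# ---------------------------------------------------------------------------


def simulate_factorial_frequencies(
    n_irs: int = 300,
    guides=("sgG2", "sgG3"),
    ssodn_levels=(False, True),
    shares: dict | None = None,
    total_sd: float = 0.12,
    mean: float = 0.45,
    seed: int = 0,
    promoters=tuple(p for p, _ in PROMOTER_WEIGHTS_POOL),
) -> pd.DataFrame:
    """Per-IR mutation frequencies from an additive factorial model.

    Effects are drawn so each factor contributes its programmed share of
    the total variance: locus effects are Gaussian, the two-level guide and
    ssODN factors use fixed +/- contrasts, and interaction effects are
    double-centered so they leak into no main effect.  Promoters are
    assigned round-robin with zero effect of their own (nested in locus, as
    in the real design).
    """
    shares = dict(shares or {"locus": 0.80, "guide": 0.12, "interaction": 0.05, "ssodn": 0.005})
    resid = 1.0 - sum(shares.values())
    if resid < 0:
        raise ValueError("variance shares exceed 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFAC7]))
    g = len(guides)
    s = len(ssodn_levels)
    locus_eff = rng.normal(0.0, 1.0, size=n_irs)
    locus_eff = (locus_eff - locus_eff.mean()) / locus_eff.std()
    locus_eff *= total_sd * math.sqrt(shares.get("locus", 0.0))
    guide_contrast = np.linspace(-1, 1, g) if g > 1 else np.zeros(1)
    guide_contrast = guide_contrast / (guide_contrast.std() if g > 1 else 1.0)
    guide_eff = guide_contrast * total_sd * math.sqrt(shares.get("guide", 0.0))
    ssodn_contrast = np.linspace(-1, 1, s) if s > 1 else np.zeros(1)
    ssodn_contrast = ssodn_contrast / (ssodn_contrast.std() if s > 1 else 1.0)
    ssodn_eff = ssodn_contrast * total_sd * math.sqrt(shares.get("ssodn", 0.0))
    inter = rng.normal(0.0, 1.0, size=(n_irs, g))
    inter = inter - inter.mean(axis=0, keepdims=True) - inter.mean(axis=1, keepdims=True) + inter.mean()
    denom = inter.std() if inter.std() > 0 else 1.0
    inter = inter / denom * total_sd * math.sqrt(shares.get("interaction", 0.0))
    rows = []
    for i in range(n_irs):
        locus = f"IR{i + 1:04d}"
        prom = promoters[i % len(promoters)]
        for gi, guide in enumerate(guides):
            for si, ss in enumerate(ssodn_levels):
                noise = rng.normal(0.0, total_sd * math.sqrt(max(resid, 0.0)))
                y = mean + locus_eff[i] + guide_eff[gi] + ssodn_eff[si] + inter[i, gi] + noise
                rows.append(
                    {
                        "barcode": locus, "promoter": prom, "guide": guide,
                        "ssodn": bool(ss), "assay": f"{guide}{'+' if ss else '-'}ssODN",
                        "total_mut_freq": float(np.clip(y, 0.001, 0.999)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature tracks
# ---------------------------------------------------------------------------


def simulate_feature_tracks(
    library,
    effect_spec: dict,
    signal,
    seed: int = 0,
    half_width: int = 1500,
):
    """Feature tracks with a requested Pearson correlation to a per-IR signal.

    ``effect_spec`` maps track name -> (category, target r).  Each track
    scores a window around every locus as ``r * z(signal) + sqrt(1-r^2) *
    noise``; the realized correlation approaches the request as the number
    of IRs grows.  Requested |r| >= 1 is an error.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(library):
        raise ValueError("signal must have one value per IR")
    z = (signal - signal.mean()) / (signal.std() if signal.std() > 0 else 1.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF7AC]))
    tracks = {}
    for name, (category, r) in effect_spec.items():
        if abs(r) >= 1.0:
            raise ValueError(f"requested |r| >= 1 for track {name}")
        noise = rng.normal(0.0, 1.0, size=len(library))
        x = r * z + math.sqrt(1.0 - r * r) * noise
        rows = []
        for c, value in zip(library, x):
            chrom, pos, _ = c.locus
            rows.append(
                {"chromosome": chrom, "start": max(0, pos - half_width),
                 "end": pos + half_width, "score": float(value)}
            )
        data = (
            pd.DataFrame(rows)
            .sort_values(["chromosome", "start"])
            .reset_index(drop=True)
        )
        tracks[name] = FeatureTrack(name=name, category=category, data=data)
    return tracks


# ---------------------------------------------------------------------------
# Hairpin (DSB end-structure) reads
# ---------------------------------------------------------------------------


def simulate_hcodes_reads(
    duplex: str,
    pam_index: int,
    structure_mixture: dict,
    n: int,
    bisulfite_failure_rate: float = 0.0,
    converted_strand: str = "bottom",
    rng: np.random.Generator | None = None,
):
    """Simulate hairpin-capture reads from a mixture of end structures.

    Each read is the expected hairpin pattern of a sampled structure with
    per-C conversion-failure substitutions (C->T) injected on the declared
    strand.  Bisulfite chemistry is abstracted: the reference is kept in
    untreated space and failed conversions surface as substitution noise,
    which downstream masking removes.  Returns (reads, truth labels).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    structures = list(structure_mixture)
    weights = np.array([structure_mixture[s] for s in structures], dtype=float)
    if weights.min() < 0 or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("structure mixture weights must be non-negative and sum to 1")
    if converted_strand not in ("bottom", "top"):
        raise ValueError("converted_strand must be 'bottom' or 'top'")
    expected = {s: expected_hairpin_read(duplex, pam_index, s) for s in structures}
    reads = []
    truth = []
    choices = rng.choice(len(structures), size=n, p=weights)
    for k in choices:
        s = structures[int(k)]
        seq = expected[s]
        bottom_len = len(duplex) - (pam_index - s.t_terminus)
        if bisulfite_failure_rate > 0:
            chars = list(seq)
            span = range(0, bottom_len) if converted_strand == "bottom" else range(bottom_len, len(seq))
            for i in span:
                if chars[i] == "C" and rng.random() < bisulfite_failure_rate:
                    chars[i] = "T"
            seq = "".join(chars)
        reads.append(seq)
        truth.append(s.label)
    return reads, truth
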