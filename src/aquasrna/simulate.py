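"""Seeded generator of environmental-small-RNA-like samples with
ground truth.

The generator emulates the statistical structure of small-RNA
sequencing of environmental exosome/sEV fractions from an aquaculture
setting: an rRNA-dominated category mix, a low target-species mapping
fraction (a few percent; the rest is non-target "background"
sequence), reads confined to 18-40 nt, a 25-32 nt piRNA class with a
tunable U-start fraction, and tandem-repeat contaminants.

Construction guarantees unambiguity: every planted role sequence is an
exact substring of the synthetic genome, reads of each class are drawn
so that no cascade rule other than the intended one can fire (verified
against the same matchers the pipeline uses, with resampling on the
rare collision), and piRNA-class reads never overlap planted
non-coding loci.  Classifying a generated sample therefore recovers
the generator's class mix exactly, which is what makes end-to-end
accuracy a meaningful test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from aquasrna.cascade import CascadeParams, ClassificationRecord, detect_tandem_repeat
from aquasrna.io_formats import ReferenceSet, SmallRNARead
from aquasrna.matcher import SubstringIndex, build_index, local_align_rescue, map_exact, map_one_mismatch

BASES = "ACGT"

#: Category composition of the rearing-tank survey sample
#: (genome-mapped reads only), used by the ``tank`` preset.
TANK_COMPOSITION: dict[str, int] = {
    "piRNA": 19_248,
    "miRNA": 27,
    "rRNA": 373_789,
    "tRNA": 45_384,
    "snRNA": 1_239,
    "other_ncRNAs": 2_293,
    "unknown": 338_564,
}

#: Composition of the largest aquaculture-site survey sample.
AQUACULTURE_COMPOSITION: dict[str, int] = {
    "piRNA": 372,
    "miRNA": 30,
    "rRNA": 361_592,
    "tRNA": 4_174,
    "snRNA": 1_638,
    "other_ncRNAs": 830,
    "unknown": 8_702,
}


def _mix_from_composition(composition: Mapping[str, int], mapped_fraction: float) -> dict[str, float]:
    total = sum(composition.values())
    mix = {cat: mapped_fraction * n / total for cat, n in composition.items()}
    mix["background"] = 1.0 - mapped_fraction
    return mix


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic sample.

    ``class_mix`` gives per-read class probabilities over the seven
    count-table categories plus ``background`` (reads that do not map
    to the target genome); it must sum to 1.  ``u_fraction`` is the
    probability that a piRNA-class read starts with T (=U).
    ``repeat_fraction`` is the fraction of unknown-class reads drawn
    from planted tandem-repeat stretches; ``rescue_fraction`` the
    fraction of rRNA-class reads drawn from rescue-only rRNA
    references (annotatable only via local alignment);
    ``known_fraction`` the fraction of piRNA-class reads that are
    exact copies of known-catalog piRNAs.  ``short_fraction`` replaces
    that fraction of reads with sub-window inserts (dropped during
    preprocessing).  ``error_rate`` adds per-base substitutions after
    truth is recorded (off by default: the exact-match stages would
    silently reclassify erroneous reads).
    """

    seed: int = 0
    n_reads: int = 10_000
    genome_length: int = 50_000
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: _mix_from_composition(TANK_COMPOSITION, 0.046)
    )
    u_fraction: float = 0.191
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    length_distributions: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "piRNA": (25, 32),
            "miRNA": (20, 24),
            "rRNA": (18, 40),
            "tRNA": (18, 40),
            "snRNA": (18, 40),
            "other_ncRNAs": (18, 40),
            "unknown": (18, 40),
            "background": (18, 40),
        }
    )
    repeat_fraction: float = 0.1
    rescue_fraction: float = 0.1
    known_fraction: float = 0.05
    short_fraction: float = 0.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix sums to {total!r}, expected 1")
        if not 0.0 <= self.u_fraction <= 1.0:
            raise ValueError("u_fraction must be in [0, 1]")
        for frac in (self.repeat_fraction, self.rescue_fraction, self.known_fraction, self.short_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


def tank_preset(seed: int = 0, n_reads: int = 10_000, **overrides) -> SimulationConfig:
    """Rearing-tank-like sample: ~4.6% genome-mapped, rRNA-dominated."""
    return SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        class_mix=_mix_from_composition(TANK_COMPOSITION, 0.046),
        u_fraction=0.191,
        **overrides,
    )


def aquaculture_preset(seed: int = 0, n_reads: int = 10_000, **overrides) -> SimulationConfig:
    """Open-water aquaculture-like sample: ~2.8% genome-mapped."""
    return SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        class_mix=_mix_from_composition(AQUACULTURE_COMPOSITION, 0.028),
        u_fraction=0.154,
        **overrides,
    )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated read."""

    read_id: str
    true_category: str
    origin_ref_id: str
    planted_first_base: str


@dataclass
class SyntheticReferences:
    """A synthetic genome with per-role reference sets planted in it.

    ``loci`` records the genome interval each role sequence (and each
    tandem-repeat stretch) occupies, so read generation can avoid
    them; ``ssr_loci`` are ``(start, end, motif)`` triples.
    """

    bundle: dict[str, ReferenceSet]
    loci: dict[str, list[tuple[int, int]]]
    ssr_loci: list[tuple[int, int, str]]

    @property
    def genome(self) -> str:
        return self.bundle["genome"].records[0][1]

    def occupied(self) -> list[tuple[int, int]]:
        out = [iv for ivs in self.loci.values() for iv in ivs]
        out.extend((s, e) for s, e, _ in self.ssr_loci)
        return sorted(out)


#: (count, min_len, max_len) of planted sequences per role.
_ROLE_PLAN: dict[str, tuple[int, int, int]] = {
    "rrna": (3, 300, 500),
    "trna": (4, 70, 90),
    "snrna": (2, 100, 150),
    "other_ncrna": (3, 80, 200),
    "mirna": (10, 20, 24),
    "known_pirna": (20, 25, 32),
    "rrna_rescue": (2, 300, 400),
}

_SSR_PLAN = 3  # planted repeat stretches
_SSR_STRETCH = 60


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


def _overlaps(start: int, end: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in intervals)


def generate_references(config: SimulationConfig) -> SyntheticReferences:
    """Build a random genome with role sequences planted as exact
    substrings at disjoint, recorded loci.

    Planted miRNA and known-piRNA sequences are validated against the
    other reference sets (no exact non-coding hit, no local-alignment
    rescue, no tandem-repeat call) and their loci re-randomised on the
    rare collision, so reads copied from them classify as intended.
    Raises ``ValueError`` when the genome is too small for ten times
    the total reference footprint.
    """
    rng = random.Random(config.seed)
    footprint = sum(n * max_len for n, _, max_len in _ROLE_PLAN.values()) + _SSR_PLAN * _SSR_STRETCH
    if config.genome_length < 10 * footprint:
        raise ValueError(
            f"genome_length {config.genome_length} < 10x reference footprint {footprint}"
        )
    genome = list(_random_seq(rng, config.genome_length))
    taken: list[tuple[int, int]] = []
    loci: dict[str, list[tuple[int, int]]] = {}
    ssr_loci: list[tuple[int, int, str]] = []

    def place(length: int) -> tuple[int, int]:
        for _ in range(10_000):
            start = rng.randrange(0, config.genome_length - length)
            if not _overlaps(start, start + length, taken):
                taken.append((start, start + length))
                return start, start + length
        raise ValueError("could not place reference sequence; genome too crowded")

    for role, (count, min_len, max_len) in _ROLE_PLAN.items():
        loci[role] = [place(rng.randint(min_len, max_len)) for _ in range(count)]
    for i in range(_SSR_PLAN):
        motif_len = rng.randint(1, 3)
        motif = _random_seq(rng, motif_len)
        start, end = place(_SSR_STRETCH)
        stretch = (motif * (_SSR_STRETCH // motif_len + 1))[:_SSR_STRETCH]
        genome[start:end] = stretch
        ssr_loci.append((start, end, motif))

    genome_str = "".join(genome)

    def role_set(role: str, prefix: str) -> ReferenceSet:
        records = tuple(
            (f"{prefix}{i + 1}", genome_str[s:e]) for i, (s, e) in enumerate(loci[role])
        )
        return ReferenceSet(name=f"synthetic_{role}", role=role, records=records)

    bundle: dict[str, ReferenceSet] = {
        "genome": ReferenceSet("synthetic_genome", "genome", (("chr1", genome_str),)),
        "rrna": role_set("rrna", "rRNA_"),
        "trna": role_set("trna", "tRNA_"),
        "snrna": role_set("snrna", "snRNA_"),
        "other_ncrna": role_set("other_ncrna", "ncRNA_"),
        "mirna": role_set("mirna", "miR_"),
        "known_pirna": role_set("known_pirna", "piR_"),
        "rrna_rescue": role_set("rrna_rescue", "rescue_rRNA_"),
    }
    refs = SyntheticReferences(bundle, loci, ssr_loci)
    _validate_planted(refs, config, rng)
    return refs


def _validate_planted(refs: SyntheticReferences, config: SimulationConfig, rng: random.Random) -> None:
    """Re-randomise planted miRNA / known-piRNA loci that collide with
    a higher-priority cascade rule (vanishingly rare, but construction
    must guarantee unambiguity)."""
    cascade = CascadeParams()
    for role in ("mirna", "known_pirna"):
        for attempt in range(100):
            nc_indexes = {
                r: build_index(refs.bundle[r]) for r in ("rrna", "trna", "snrna", "other_ncrna")
            }
            bad: list[int] = []
            for i, (rid, seq) in enumerate(refs.bundle[role].records):
                collides = any(map_exact(seq, idx) for idx in nc_indexes.values())
                if not collides and local_align_rescue(
                    seq, refs.bundle["rrna_rescue"],
                    cascade.rescue_min_identity, cascade.rescue_min_coverage,
                ):
                    collides = True
                if not collides and role == "known_pirna" and detect_tandem_repeat(seq, cascade).is_repeat:
                    collides = True
                if collides:
                    bad.append(i)
            if not bad:
                break
            genome = list(refs.genome)
            for i in bad:
                s, e = refs.loci[role][i]
                genome[s:e] = _random_seq(rng, e - s)
            genome_str = "".join(genome)
            refs.bundle["genome"] = ReferenceSet("synthetic_genome", "genome", (("chr1", genome_str),))
            prefix = {"mirna": "miR_", "known_pirna": "piR_"}[role]
            refs.bundle[role] = ReferenceSet(
                f"synthetic_{role}",
                role,
                tuple(
                    (f"{prefix}{i + 1}", genome_str[s:e])
                    for i, (s, e) in enumerate(refs.loci[role])
                ),
            )
        else:  # pragma: no cover
            raise RuntimeError(f"could not plant unambiguous {role} references")


class _ReadSampler:
    """Draws class-labelled inserts from a planted reference layout,
    verifying unambiguity against the pipeline's own matchers."""

    def __init__(self, refs: SyntheticReferences, config: SimulationConfig, rng: random.Random):
        self.refs = refs
        self.config = config
        self.rng = rng
        self.cascade = CascadeParams()
        self.genome = refs.genome
        self.occupied = refs.occupied()
        self.nc_indexes: dict[str, SubstringIndex] = {
            r: build_index(refs.bundle[r]) for r in ("rrna", "trna", "snrna", "other_ncrna")
        }
        self.mirna_index = build_index(refs.bundle["mirna"])
        self.genome_index = build_index(refs.bundle["genome"])

    # -- helpers -----------------------------------------------------------

    def _len(self, category: str) -> int:
        lo, hi = self.config.length_distributions[category]
        return self.rng.randint(lo, hi)

    def _hits_ncrna(self, seq: str, above: Sequence[str]) -> bool:
        return any(map_exact(seq, self.nc_indexes[r]) for r in above)

    def _rescued(self, seq: str) -> bool:
        return (
            local_align_rescue(
                seq, self.refs.bundle["rrna_rescue"],
                self.cascade.rescue_min_identity, self.cascade.rescue_min_coverage,
            )
            is not None
        )

    def _free_genome_substring(self, length: int, first_base: str | None = None) -> tuple[str, int]:
        for _ in range(100_000):
            start = self.rng.randrange(0, len(self.genome) - length)
            if _overlaps(start, start + length, self.occupied):
                continue
            seq = self.genome[start : start + length]
            if first_base is not None and seq[0] != first_base:
                continue
            return seq, start
        raise RuntimeError("failed to sample a free genome substring")  # pragma: no cover

    # -- per-class insert sampling ----------------------------------------

    def sample(self, category: str) -> tuple[str, str]:
        """Return (insert sequence, origin id) for one read of ``category``."""
        return getattr(self, f"_sample_{category.lower().replace('_', '')}")()

    def _from_reference(self, role: str, above: Sequence[str]) -> tuple[str, str]:
        cat = {"rrna": "rRNA", "trna": "tRNA", "snrna": "snRNA", "other_ncrna": "other_ncRNAs"}[role]
        records = self.refs.bundle[role].records
        while True:
            rid, ref_seq = records[self.rng.randrange(len(records))]
            length = min(self._len(cat), len(ref_seq))
            start = self.rng.randrange(0, len(ref_seq) - length + 1)
            seq = ref_seq[start : start + length]
            if not self._hits_ncrna(seq, above):
                return seq, rid

    def _sample_rrna(self) -> tuple[str, str]:
        if self.rng.random() < self.config.rescue_fraction:
            records = self.refs.bundle["rrna_rescue"].records
            while True:
                rid, ref_seq = records[self.rng.randrange(len(records))]
                length = min(self._len("rRNA"), len(ref_seq))
                start = self.rng.randrange(0, len(ref_seq) - length + 1)
                seq = ref_seq[start : start + length]
                # must reach the rescue rule, and the rescue must succeed
                if not self._hits_ncrna(seq, ("trna", "snrna", "other_ncrna")) and self._rescued(seq):
                    return seq, rid
        return self._from_reference("rrna", ())

    def _sample_trna(self) -> tuple[str, str]:
        return self._from_reference("trna", ("rrna",))

    def _sample_snrna(self) -> tuple[str, str]:
        return self._from_reference("snrna", ("rrna", "trna"))

    def _sample_otherncrnas(self) -> tuple[str, str]:
        return self._from_reference("other_ncrna", ("rrna", "trna", "snrna"))

    def _sample_mirna(self) -> tuple[str, str]:
        records = self.refs.bundle["mirna"].records
        rid, seq = records[self.rng.randrange(len(records))]
        return seq, rid  # planted refs pre-validated against other rules

    def _sample_pirna(self) -> tuple[str, str]:
        if self.rng.random() < self.config.known_fraction:
            records = self.refs.bundle["known_pirna"].records
            rid, seq = records[self.rng.randrange(len(records))]
            return seq, rid
        want_u = self.rng.random() < self.config.u_fraction
        all_nc = ("rrna", "trna", "snrna", "other_ncrna")
        while True:
            seq, start = self._free_genome_substring(self._len("piRNA"), "T" if want_u else None)
            if not want_u and seq[0] == "T":
                continue
            if self._hits_ncrna(seq, all_nc):
                continue
            if detect_tandem_repeat(seq, self.cascade).is_repeat:
                continue
            if self._rescued(seq):
                continue
            return seq, f"chr1:{start}"

    def _sample_unknown(self) -> tuple[str, str]:
        if self.rng.random() < self.config.repeat_fraction:
            return self._sample_ssr()
        all_nc = ("rrna", "trna", "snrna", "other_ncrna")
        lo, hi = self.config.length_distributions["unknown"]
        p_lo, p_hi = self.cascade.pirna_min_len, self.cascade.pirna_max_len
        lengths = [n for n in range(lo, hi + 1) if not p_lo <= n <= p_hi]
        while True:
            seq, start = self._free_genome_substring(self.rng.choice(lengths))
            if self._hits_ncrna(seq, all_nc):
                continue
            if map_one_mismatch(seq, self.mirna_index):
                continue
            if detect_tandem_repeat(seq, self.cascade).is_repeat:
                continue
            if self._rescued(seq):
                continue
            return seq, f"chr1:{start}"

    def _sample_ssr(self) -> tuple[str, str]:
        all_nc = ("rrna", "trna", "snrna", "other_ncrna")
        lo, hi = self.config.length_distributions["unknown"]
        while True:
            s, e, motif = self.refs.ssr_loci[self.rng.randrange(len(self.refs.ssr_loci))]
            length = self.rng.randint(lo, hi)
            start = self.rng.randrange(s, e - length + 1)
            seq = self.genome[start : start + length]
            if not detect_tandem_repeat(seq, self.cascade).is_repeat:
                continue
            if self._hits_ncrna(seq, all_nc) or map_one_mismatch(seq, self.mirna_index):
                continue
            if self._rescued(seq):
                continue
            return seq, f"ssr:({motif})"

    def _sample_background(self) -> tuple[str, str]:
        while True:
            seq = _random_seq(self.rng, self._len("background"))
            if not map_exact(seq, self.genome_index):
                return seq, "background"

    def _sample_tooshort(self) -> tuple[str, str]:
        length = self.rng.randint(10, self.cascade.pirna_min_len - 8)  # < 18 nt
        seq, start = self._free_genome_substring(length)
        return seq, f"chr1:{start}"


def generate_reads(
    config: SimulationConfig, refs: SyntheticReferences
) -> tuple[list[SmallRNARead], list[TruthRecord]]:
    """Draw a synthetic sample of raw reads with per-read ground truth.

    Each read is an insert drawn per ``class_mix`` and decorated the
    way the library chemistry leaves it: 4 random bases on each side
    of the insert and the 3' adapter appended, with uniform Q40
    qualities.  Running the preprocessing stage with its defaults
    recovers the inserts exactly.  Output is deterministic for a given
    config (byte-identical FASTQ on rerun).
    """
    rng = random.Random(config.seed + 1)
    sampler = _ReadSampler(refs, config, rng)
    categories = sorted(config.class_mix)
    weights = [config.class_mix[c] for c in categories]
    reads: list[SmallRNARead] = []
    truth: list[TruthRecord] = []
    width = max(6, len(str(config.n_reads)))
    for i in range(config.n_reads):
        read_id = f"r{i:0{width}d}"
        if config.short_fraction and rng.random() < config.short_fraction:
            category = "too_short"
            insert, origin = sampler._sample_tooshort()
        else:
            category = rng.choices(categories, weights)[0]
            insert, origin = sampler.sample(category)
        if config.error_rate:
            insert = "".join(
                rng.choice([b for b in BASES if b != base]) if rng.random() < config.error_rate else base
                for base in insert
            )
        raw = _random_seq(rng, 4) + insert + _random_seq(rng, 4) + config.adapter
        reads.append(SmallRNARead(read_id, raw, (40,) * len(raw)))
        truth.append(TruthRecord(read_id, category, origin, insert[0]))
    return reads, truth


def write_truth_tsv(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_category\torigin_ref_id\tplanted_first_base\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.true_category}\t{t.origin_ref_id}\t{t.planted_first_base}\n")


def read_truth_tsv(path) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"{path}: not a truth TSV")
        for line in fh:
            read_id, cat, origin, first = line.rstrip("\n").split("\t")
            out.append(TruthRecord(read_id, cat, origin, first))
    return out


@dataclass
class RecoveryResult:
    """Confusion matrix of true vs predicted categories."""

    categories: list[str]
    matrix: dict[tuple[str, str], int]
    overall_accuracy: float
    per_class_accuracy: dict[str, float]


def evaluate_recovery(
    truth: Sequence[TruthRecord],
    records: Sequence[ClassificationRecord],
    unmapped_read_ids: Iterable[str] = (),
    dropped_read_ids: Iterable[str] = (),
) -> RecoveryResult:
    """Compare classification output against generator ground truth.

    Reads excluded at the genome gate are scored as predicted
    ``background``; reads dropped in preprocessing as ``too_short``.
    The union of ``records``, ``unmapped_read_ids`` and
    ``dropped_read_ids`` must cover exactly the truth read ids.
    """
    if not truth:
        raise ValueError("empty truth table")
    predicted: dict[str, str] = {r.read_id: r.category for r in records}
    for rid in unmapped_read_ids:
        predicted[rid] = "background"
    for rid in dropped_read_ids:
        predicted[rid] = "too_short"
    truth_ids = {t.read_id for t in truth}
    if truth_ids != set(predicted):
        missing = truth_ids - set(predicted)
        extra = set(predicted) - truth_ids
        raise ValueError(
            f"read id mismatch between truth and predictions "
            f"({len(missing)} missing, {len(extra)} extra)"
        )
    cats = sorted({t.true_category for t in truth} | set(predicted.values()))
    matrix = {(a, b): 0 for a in cats for b in cats}
    for t in truth:
        matrix[(t.true_category, predicted[t.read_id])] += 1
    correct = sum(matrix[(c, c)] for c in cats)
    per_class: dict[str, float] = {}
    for c in cats:
        row_total = sum(matrix[(c, b)] for b in cats)
        if row_total:
            per_class[c] = matrix[(c, c)] / row_total
    return RecoveryResult(cats, matrix, correct / len(truth), per_class)
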