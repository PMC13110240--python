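"""End-to-end orchestration: a configured run from FASTQ to the four
report tables plus a machine-readable manifest.

A run is linear per sample — preprocess, genome-gate + annotation
cascade, piRNA statistics, known-catalog matching — followed by
cross-sample aggregation.  All outputs are TSV/FASTA/JSON and a rerun
with identical inputs is byte-identical (no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from aquasrna.cascade import CascadeParams, classify_sample
from aquasrna.io_formats import (
    CATEGORY_ORDER,
    ConfigError,
    REFERENCE_ROLES,
    load_reference_bundle,
    read_fastq,
    write_count_table,
    write_fasta,
)
from aquasrna.pirna_stats import (
    OccurrenceTable,
    aggregate_bias,
    category_fraction,
    first_base_bias,
    match_known_pirnas,
    top_sequences,
)
from aquasrna.preprocess import PreprocessParams, preprocess_reads

logger = logging.getLogger("aquasrna")

_KNOWN_KEYS = {
    "samples",
    "references",
    "preprocess",
    "cascade",
    "output_dir",
    "top_n",
    "log_level",
}


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    samples: list[dict[str, str]]
    references: dict[str, str]
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cascade: CascadeParams = field(default_factory=CascadeParams)
    output_dir: str = "aquasrna_out"
    top_n: int = 5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        problems = validate_config(raw, base_dir=os.path.dirname(os.path.abspath(path)))
        if problems:
            raise ConfigError(f"{path}: " + "; ".join(problems))
        return cls._from_mapping(raw, base_dir=os.path.dirname(os.path.abspath(path)))

    @classmethod
    def _from_mapping(cls, raw: Mapping[str, Any], base_dir: str = ".") -> "PipelineConfig":
        def resolve(p: str) -> str:
            return p if os.path.isabs(p) else os.path.join(base_dir, p)

        samples = [
            {"id": s["id"], "fastq": resolve(s["fastq"])} for s in raw["samples"]
        ]
        references = {role: resolve(p) for role, p in raw["references"].items()}
        pp = PreprocessParams(**raw.get("preprocess", {}))
        cc = CascadeParams(**raw.get("cascade", {}))
        return cls(
            samples=samples,
            references=references,
            preprocess=pp,
            cascade=cc,
            output_dir=resolve(raw.get("output_dir", "aquasrna_out")),
            top_n=int(raw.get("top_n", 5)),
            log_level=str(raw.get("log_level", "INFO")),
        )


def validate_config(raw: Mapping[str, Any], base_dir: str = ".") -> list[str]:
    """Check a parsed config mapping; returns a list of problems
    (empty means valid).  Never mutates state."""
    problems: list[str] = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            problems.append(f"unknown top-level key {key!r}")
    samples = raw.get("samples")
    if not isinstance(samples, list) or not samples:
        problems.append("'samples' must be a non-empty list")
        samples = []
    for i, s in enumerate(samples):
        if not isinstance(s, dict) or "id" not in s or "fastq" not in s:
            problems.append(f"sample #{i}: needs 'id' and 'fastq'")
            continue
        path = s["fastq"]
        full = path if os.path.isabs(path) else os.path.join(base_dir, path)
        if not os.path.exists(full):
            problems.append(f"sample {s['id']!r}: FASTQ not found: {path}")
    refs = raw.get("references")
    if not isinstance(refs, dict):
        problems.append("'references' must be a mapping role -> FASTA path")
        refs = {}
    for role, path in refs.items():
        if role not in REFERENCE_ROLES:
            problems.append(f"unknown reference role {role!r}")
            continue
        full = path if os.path.isabs(path) else os.path.join(base_dir, path)
        if not os.path.exists(full):
            problems.append(f"reference {role!r}: FASTA not found: {path}")
    for section, cls in (("preprocess", PreprocessParams), ("cascade", CascadeParams)):
        params = raw.get(section, {})
        if not isinstance(params, dict):
            problems.append(f"'{section}' must be a mapping")
            continue
        try:
            cls(**params)
        except (TypeError, ValueError) as err:
            problems.append(f"{section}: {err}")
    return problems


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute a full run and return the report directory.

    Per sample: ``<id>_counts.tsv`` (category counts),
    ``<id>_bias.tsv`` (1U bias at both levels), ``<id>_top.tsv``
    (top-N piRNAs), ``<id>_known_matches.tsv`` (catalog matches),
    ``<id>_pirna.fasta`` (predicted piRNAs with occurrence counts in
    headers) and ``<id>_dropstats.tsv``.  Across samples:
    ``aggregate_bias.tsv`` (mean +/- n-1 SD, when >= 2 samples) and
    ``manifest.json`` recording every parameter and input checksum.
    Any stage error aborts with the stage and sample named.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("loading reference bundle (%d roles)", len(config.references))
    bundle = load_reference_bundle(config.references)

    manifest: dict[str, Any] = {
        "package": "aquasrna",
        "parameters": {
            "preprocess": asdict(config.preprocess),
            "cascade": {
                **{k: v for k, v in asdict(config.cascade).items() if k != "ssr_min_repeats"},
                "ssr_min_repeats": {str(k): v for k, v in config.cascade.ssr_min_repeats.items()},
            },
            "top_n": config.top_n,
        },
        "inputs": {
            "references": {role: _sha256(p) for role, p in sorted(config.references.items())},
            "samples": {},
        },
        "samples": {},
    }

    summaries = []
    for sample in config.samples:
        sid, fastq = sample["id"], sample["fastq"]
        manifest["inputs"]["samples"][sid] = _sha256(fastq)
        try:
            reads = read_fastq(fastq)
            logger.info("[%s] %d raw reads", sid, len(reads))
            kept, drop_stats = preprocess_reads(reads, config.preprocess)
            logger.info("[%s] preprocess: kept=%d drops=%s", sid, len(kept), drop_stats)
        except Exception as err:
            raise RuntimeError(f"stage 'preprocess' failed for sample {sid!r}: {err}") from err
        try:
            result = classify_sample(kept, bundle, config.cascade, sample_id=sid)
            logger.info(
                "[%s] classify: classified=%d unmapped=%d skipped=%s",
                sid, result.count_table.total, len(result.unmapped_read_ids), result.skipped_stages,
            )
        except Exception as err:
            raise RuntimeError(f"stage 'classify' failed for sample {sid!r}: {err}") from err

        write_count_table(result.count_table, out / f"{sid}_counts.tsv")
        with open(out / f"{sid}_dropstats.tsv", "w") as fh:
            fh.write("reason\tcount\n")
            for reason, n in sorted(drop_stats.items()):
                fh.write(f"{reason}\t{n}\n")
            fh.write(f"unmapped\t{len(result.unmapped_read_ids)}\n")
            fh.write(f"classified\t{result.count_table.total}\n")

        occ = OccurrenceTable.from_occurrences(sid, result.pirna_occurrences)
        write_fasta(
            ((f"{sid}_piRNA_{i + 1}_x{count}", seq) for i, (seq, _l, count) in enumerate(occ.entries)),
            out / f"{sid}_pirna.fasta",
        )
        with open(out / f"{sid}_top.tsv", "w") as fh:
            fh.write("rank\tsequence\tlength\tcount\n")
            if occ.entries:
                for rank, seq, length, count in top_sequences(occ, config.top_n):
                    fh.write(f"{rank}\t{seq}\t{length}\t{count}\n")

        bias = None
        if occ.entries:
            bias = first_base_bias(occ)
            summaries.append(bias)
        with open(out / f"{sid}_bias.tsv", "w") as fh:
            fh.write(
                "sample\tu_types\tnon_u_types\tbias_types_pct\tu_freq\tnon_u_freq\tbias_freq_pct\n"
            )
            if bias is not None:
                fh.write(
                    f"{sid}\t{bias.u_types}\t{bias.non_u_types}\t{bias.bias_types_pct}\t"
                    f"{bias.u_freq}\t{bias.non_u_freq}\t{bias.bias_freq_pct}\n"
                )

        with open(out / f"{sid}_known_matches.tsv", "w") as fh:
            fh.write("sequence\tcount\tcatalog_id\n")
            if "known_pirna" in bundle:
                for seq, count, cid in match_known_pirnas(occ, bundle["known_pirna"]):
                    fh.write(f"{seq}\t{count}\t{cid}\n")
            else:
                logger.info("[%s] known-piRNA matching skipped: no catalog configured", sid)

        manifest["samples"][sid] = {
            "raw_reads": len(reads),
            "kept_reads": len(kept),
            "drop_stats": dict(sorted(drop_stats.items())),
            "unmapped": len(result.unmapped_read_ids),
            "skipped_stages": result.skipped_stages,
            "counts": {cat: result.count_table.rows[cat] for cat in CATEGORY_ORDER},
            "pirna_fraction_pct": (
                category_fraction(result.count_table, "piRNA")
                if result.count_table.total
                else None
            ),
        }

    with open(out / "aggregate_bias.tsv", "w") as fh:
        fh.write("level\tmean_pct\tsd_pct\tn_samples\n")
        if len(summaries) >= 2:
            for level in ("types", "frequencies"):
                agg = aggregate_bias(summaries, level)
                fh.write(f"{level}\t{agg.mean_pct}\t{agg.sd_pct}\t{agg.n_samples}\n")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return out
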