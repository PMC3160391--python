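"""End-to-end pipeline: simulate -> map -> profile -> estimate.

One YAML config drives the whole experiment: a synthetic genome with known
repeat truth is built, a BAC-like reference is drawn from it, Cot-selected
read sets are simulated at the configured Cot values, mapped under the
identity/coverage thresholds, profiled in windows, and the per-fraction
element read fractions are extrapolated to Cot zero to estimate the
element's genome-wide copy number — which the report then compares to the
simulator's ground truth.

A single global seed is fanned out to per-stage child seeds by a stable
hash so any stage can be rerun independently; outputs are bit-reproducible
under a fixed seed (timings live only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .depth import DepthProfile
from .frequency import (
    FractionCount,
    config_hash,
    element_read_fraction,
    estimate_copies,
    frequency_report,
)
from .intervals import GenomicInterval
from .mapping import MappingConfig, ReferenceIndex, map_reads
from .simulate import (
    DEFAULT_K_BASE,
    DEFAULT_READ_LEN_MEAN,
    DEFAULT_READ_LEN_SD,
    RepeatFamilySpec,
    TandemArraySpec,
    build_genome,
    sample_bac,
    simulate_cot_fraction,
    write_reads,
    write_truth_table_tsv,
)
from .seqio import write_bed, write_fasta

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "genome",
    "bac_length",
    "cot_values",
    "n_reads",
    "read_len_mean",
    "read_len_sd",
    "k_base",
    "mapping",
    "window",
    "genome_size",
    "extrapolation_mode",
    "element_family",
    "seed",
    "outdir",
}
_KNOWN_GENOME_KEYS = {"background_length", "families", "arrays", "ref_id"}
_KNOWN_FAMILY_KEYS = {
    "family_id",
    "consensus",
    "consensus_length",
    "copy_number",
    "divergence",
    "indel_rate",
}
_KNOWN_MAPPING_KEYS = {"min_identity", "min_read_coverage", "seed_word"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class ConfigError(ValueError):
    """All config problems collected into one error."""

    def __init__(self, errors: list):
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))
        self.errors = errors


def derive_seed(master_seed: int, label: str) -> int:
    """Stable, machine-independent child seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    genome: dict = field(default_factory=lambda: dict(DEFAULT_GENOME_SPEC))
    bac_length: int | None = None  # None -> whole genome as reference
    cot_values: list = field(default_factory=lambda: [69.56, 695.6])
    n_reads: int = 5000
    read_len_mean: float = DEFAULT_READ_LEN_MEAN
    read_len_sd: float = DEFAULT_READ_LEN_SD
    k_base: float = DEFAULT_K_BASE
    mapping: dict = field(
        default_factory=lambda: {
            "min_identity": 1.0,
            "min_read_coverage": 0.9,
            "seed_word": 16,
        }
    )
    window: int = 100
    genome_size: float | None = None  # None -> synthetic genome length
    extrapolation_mode: str = "linear"
    element_family: str | None = None  # None -> first family in the genome spec
    seed: int = 1
    outdir: str = "cotfreq_run"

    def mapping_config(self) -> MappingConfig:
        return MappingConfig(**self.mapping)

    def as_dict(self, with_outdir: bool = False) -> dict:
        d = asdict(self)
        if not with_outdir:
            # the output location is not part of the experiment: reports and
            # config hashes must be identical wherever the run lands
            d.pop("outdir")
        return d


#: demo: a 2 Mb genome with a 195 bp SINE-like family at 500 copies
DEFAULT_GENOME_SPEC = {
    "background_length": 2_000_000,
    "families": [
        {
            "family_id": "sine1",
            "consensus_length": 195,
            "copy_number": 500,
            "divergence": 0.0,
        }
    ],
    "arrays": [],
    "ref_id": "synthetic_genome",
}


def _build_family_specs(genome_spec: dict, seed: int) -> list:
    rng = np.random.default_rng(derive_seed(seed, "family_consensus"))
    fams = []
    for f in genome_spec.get("families", []):
        consensus = f.get("consensus")
        if consensus is None:
            length = int(f["consensus_length"])
            consensus = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        fams.append(
            RepeatFamilySpec(
                family_id=f["family_id"],
                consensus=consensus,
                copy_number=int(f["copy_number"]),
                divergence=float(f.get("divergence", 0.0)),
                indel_rate=float(f.get("indel_rate", 0.0)),
            )
        )
    return fams


def _build_array_specs(genome_spec: dict) -> list:
    return [
        TandemArraySpec(
            array_id=a["array_id"],
            unit_parts=tuple((p[0], int(p[1])) for p in a["unit_parts"]),
            n_units=int(a["n_units"]),
        )
        for a in genome_spec.get("arrays", [])
    ]


def validate_config(source: str | Path | dict | None) -> tuple[RunConfig, list]:
    """Normalise a YAML config (path, dict or None) into a RunConfig.

    Collects *all* errors before raising :class:`ConfigError`; unknown keys
    are warnings (logged and returned), not errors.  An empty file yields
    all defaults.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError([f"top-level YAML must be a mapping, got {type(raw).__name__}"])

    errors: list = []
    warnings_list: list = []
    for key in sorted(set(raw) - _KNOWN_KEYS):
        warnings_list.append(f"unknown config key {key!r} ignored")
    cfg = RunConfig()
    for key in _KNOWN_KEYS & set(raw):
        if raw[key] is not None or key in ("bac_length", "genome_size", "element_family"):
            setattr(cfg, key, raw[key])

    if isinstance(cfg.genome, dict):
        for key in sorted(set(cfg.genome) - _KNOWN_GENOME_KEYS):
            warnings_list.append(f"unknown genome key {key!r} ignored")
        if int(cfg.genome.get("background_length", 0)) <= 0:
            errors.append("genome.background_length must be positive")
        for f in cfg.genome.get("families", []):
            for key in sorted(set(f) - _KNOWN_FAMILY_KEYS):
                warnings_list.append(f"unknown family key {key!r} ignored")
            if "consensus" not in f and "consensus_length" not in f:
                errors.append(f"family {f.get('family_id')}: need consensus or consensus_length")
            if int(f.get("copy_number", 0)) < 1:
                errors.append(f"family {f.get('family_id')}: copy_number must be >= 1")
    else:
        errors.append("genome must be a mapping")

    if cfg.n_reads <= 0:
        errors.append(f"n_reads must be positive, got {cfg.n_reads}")
    if len(cfg.cot_values) < 2:
        errors.append(
            "need at least two Cot values: extrapolation to Cot zero requires >= 2 "
            "fraction points (add a second cot_values entry)"
        )
    if len(set(cfg.cot_values)) != len(cfg.cot_values):
        errors.append("cot_values must be distinct")
    if any(c < 0 for c in cfg.cot_values):
        errors.append("cot_values must be non-negative")
    if cfg.k_base <= 0:
        errors.append(f"k_base must be positive, got {cfg.k_base}")
    if cfg.window < 1:
        errors.append(f"window must be >= 1, got {cfg.window}")
    if cfg.extrapolation_mode not in ("linear", "loglinear"):
        errors.append(f"unknown extrapolation_mode {cfg.extrapolation_mode!r}")
    if cfg.read_len_mean < 50:
        errors.append(f"read_len_mean must be >= 50, got {cfg.read_len_mean}")
    try:
        cfg.mapping_config()
    except ValueError as exc:
        errors.append(str(exc))

    for w in warnings_list:
        logger.warning(w)
    if errors:
        raise ConfigError(errors)
    return cfg, warnings_list


@dataclass
class PipelineResult:
    outdir: Path
    estimate: Any
    truth_copy_number: int | None
    manifest: dict


def run_pipeline(config: RunConfig | dict | str | Path | None) -> PipelineResult:
    """Run simulate -> map -> profile -> estimate; returns paths and the estimate."""
    if not isinstance(config, RunConfig):
        config, _ = validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "cotfreq",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "outdir": str(outdir),
        "config": config.as_dict(),
        "config_hash": config_hash(config.as_dict()),
        "stage_seconds": {},
        "status": "incomplete",
    }
    stage = "init"
    try:
        # --- simulate genome -------------------------------------------------
        stage = "simulate_genome"
        t0 = time.perf_counter()
        fams = _build_family_specs(config.genome, config.seed)
        arrays = _build_array_specs(config.genome)
        genome = build_genome(
            int(config.genome["background_length"]),
            fams,
            arrays,
            seed=derive_seed(config.seed, "genome"),
            ref_id=config.genome.get("ref_id", "synthetic_genome"),
        )
        write_fasta([genome.sequence], outdir / "genome.fasta")
        write_truth_table_tsv(genome, outdir / "truth.tsv")
        write_bed(
            [iv for iv, _ in genome.placements],
            outdir / "placements.bed",
            names=[fam for _, fam in genome.placements],
        )
        manifest["stage_seconds"][stage] = time.perf_counter() - t0

        # --- reference (BAC-like window or whole genome) ---------------------
        stage = "sample_reference"
        t0 = time.perf_counter()
        if config.bac_length is None:
            reference, source = genome.sequence, genome.sequence.interval("+")
        else:
            reference, source = sample_bac(
                genome, int(config.bac_length), seed=derive_seed(config.seed, "bac")
            )
        write_fasta([reference], outdir / "reference.fasta")
        manifest["reference_source"] = [source.start, source.end]
        manifest["stage_seconds"][stage] = time.perf_counter() - t0

        # --- element annotation ----------------------------------------------
        stage = "select_element"
        element_family = config.element_family or (fams[0].family_id if fams else None)
        if element_family is None:
            raise PipelineError(stage, "no repeat family to estimate")
        in_ref = [
            iv
            for iv, fam in genome.placements
            if fam == element_family and iv.start >= source.start and iv.end <= source.end
        ]
        if not in_ref:
            raise PipelineError(
                stage,
                f"no copy of family {element_family!r} inside the reference window; "
                "increase bac_length or reseed",
            )
        iv = in_ref[0]
        element = GenomicInterval(reference.ref_id, iv.start - source.start, iv.end - source.start)
        write_bed([element], outdir / "element.bed", names=[element_family])

        # --- per-fraction simulate/map/profile -------------------------------
        mapping_cfg = config.mapping_config()
        index = ReferenceIndex(reference, mapping_cfg.seed_word)
        counts: list = []
        coverages: dict = {}
        for i, cot in enumerate(config.cot_values):
            stage = f"simulate_cot_{i}"
            t0 = time.perf_counter()
            fraction = simulate_cot_fraction(
                genome,
                cot=cot,
                n_reads=int(config.n_reads),
                read_len_mean=config.read_len_mean,
                read_len_sd=config.read_len_sd,
                k_base=config.k_base,
                seed=derive_seed(config.seed, f"fraction:{i}"),
            )
            write_reads(fraction, outdir / f"reads_cot{i}.fasta", "fasta")
            manifest["stage_seconds"][stage] = time.perf_counter() - t0

            stage = f"map_cot_{i}"
            t0 = time.perf_counter()
            result = map_reads(fraction.reads, reference, mapping_cfg, index=index)
            result.to_tsv(outdir / f"alignments_cot{i}.tsv")
            manifest["stage_seconds"][stage] = time.perf_counter() - t0

            stage = f"profile_cot_{i}"
            t0 = time.perf_counter()
            if result.records:
                profile = DepthProfile.from_alignments(
                    result.records,
                    reference.ref_id,
                    reference.length,
                    window=config.window,
                    total_sequenced_reads=fraction.total_reads,
                )
                profile.to_tsv(outdir / f"profile_cot{i}.tsv")
                profile.to_bedgraph(outdir / f"profile_cot{i}.bedgraph")
                coverages[str(cot)] = profile.coverage
            else:
                coverages[str(cot)] = 0.0
            manifest["stage_seconds"][stage] = time.perf_counter() - t0

            n_element = round(
                element_read_fraction(element, result.records, fraction.total_reads)
                * fraction.total_reads
            )
            counts.append(FractionCount(cot, int(n_element), fraction.total_reads))

        # --- estimate ---------------------------------------------------------
        stage = "estimate"
        t0 = time.perf_counter()
        genome_size = (
            float(config.genome_size) if config.genome_size is not None else genome.length
        )
        estimate = estimate_copies(
            counts,
            genome_size=genome_size,
            element_length=element.length,
            mode=config.extrapolation_mode,
            element=element,
        )
        truth = genome.truth_table[element_family]
        meta = {
            "config": config.as_dict(),
            "seed": config.seed,
            "element_family": element_family,
            "coverage_fraction": coverages,
            "truth": {
                "copy_number": truth.copy_number,
                "element_length": truth.element_length,
                "genomic_fraction": truth.genomic_fraction,
            },
        }
        frequency_report(
            [estimate],
            run_metadata=meta,
            json_path=outdir / "estimate.json",
            tsv_path=outdir / "estimate.tsv",
        )
        manifest["stage_seconds"][stage] = time.perf_counter() - t0

        manifest["status"] = "complete"
        return PipelineResult(
            outdir=outdir,
            estimate=estimate,
            truth_copy_number=truth.copy_number,
            manifest=manifest,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 — annotate failures with the stage name
        raise PipelineError(stage, str(exc)) from exc
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
            fh.write("\n")
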