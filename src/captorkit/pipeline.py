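"""End-to-end desk-scale pipeline: design -> mix -> simulate -> classify ->
profile -> ladder, with all artefacts written to a directory and a JSON
manifest recording parameters, seeds and outputs.

This is the library-level equivalent of a workflow driver; every stage is
also callable on its own (see the examples/ directory).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import accumulate_events, classify_library, per_read_error
from .design import DesignConfig, design_panel, write_panel
from .errors import InvalidParameterError
from .io import write_fastq, write_json, write_tsv
from .mixture import build_staggered_manifest, write_manifest
from .profiling import kmer_table, pore_time_summary, profile_rates
from .quant import captor_counts, ladder_fit
from .simulate import (SimConfig, build_context_error_model,
                       default_pore_model, simulate_library)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters for one pipeline run; defaults mirror each stage's own."""

    rng_seed: int = 0
    design: DesignConfig = field(default_factory=DesignConfig)
    group_size: int = 9
    n_levels: int = 8
    fold: float = 2.0
    n_reads: int = 5000
    min_identity: float = 0.7
    clip: int = 500
    min_depth: int = 10
    time_bin: float = 3600.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "design" in d and isinstance(d["design"], dict):
            design_known = set(DesignConfig.__dataclass_fields__)
            bad = set(d["design"]) - design_known
            if bad:
                raise InvalidParameterError(
                    f"unknown design config keys: {sorted(bad)}")
            d["design"] = DesignConfig(**d["design"])
        return cls(**d)


def _substream(seed: int, label: str) -> int:
    """Independent per-stage seed below 2^31, derived from the run seed."""
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig | dict, out_dir,
                 sample_refs: dict[str, str] | None = None) -> dict:
    """Execute the full desk-scale pipeline; returns the artefact manifest."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "rng_seed": config.rng_seed,
                      "stages": {}, "artefacts": {}}

    # design
    design_cfg = config.design
    if design_cfg.rng_seed != config.rng_seed:
        design_cfg = DesignConfig(**{**asdict(design_cfg),
                                     "rng_seed": config.rng_seed})
    panel = design_panel(design_cfg)
    write_panel(panel, out / "panel.fasta", out / "panel.tsv")
    manifest["stages"]["design"] = asdict(design_cfg)
    manifest["artefacts"]["panel_fasta"] = "panel.fasta"

    # mixture
    mix = build_staggered_manifest([a.id for a in panel],
                                   group_size=config.group_size,
                                   n_levels=config.n_levels, fold=config.fold)
    write_manifest(mix, out / "manifest.tsv")
    manifest["artefacts"]["manifest_tsv"] = "manifest.tsv"

    # simulate
    if sample_refs is None:
        rng = np.random.default_rng(_substream(config.rng_seed, "refs"))
        sample_refs = {
            f"feature_{i + 1}": "".join("ACGT"[b] for b in
                                        rng.integers(0, 4, size=400))
            for i in range(4)}
    sim_seed = _substream(config.rng_seed, "simulate")
    model = build_context_error_model(rng_seed=sim_seed)
    pores = default_pore_model(rng_seed=sim_seed)
    sim_cfg = SimConfig(n_reads=config.n_reads, rng_seed=sim_seed)
    reads, truth = simulate_library(panel, mix, sample_refs, model, pores,
                                    sim_cfg)
    write_fastq(out / "reads.fastq", reads)
    write_tsv(truth, out / "truth.tsv")
    manifest["stages"]["simulate"] = {"n_reads": config.n_reads,
                                      "rng_seed": sim_seed}

    # classify + events
    classifications = classify_library(reads, panel,
                                       min_identity=config.min_identity,
                                       clip=config.clip)
    rows = []
    for c in classifications:
        rows.append({
            "read_id": c.read_id, "captor_id": c.captor_id,
            "orientation": c.orientation, "identity": c.identity,
            "channel": c.meta.channel if c.meta else None,
            "start_time": c.meta.start_time if c.meta else None,
            "per_read_error": (per_read_error(c, panel)
                               if c.classified else np.nan)})
    class_df = pd.DataFrame(rows)
    write_tsv(class_df, out / "classifications.tsv")
    events = accumulate_events(classifications, panel)
    profiles = {cid: profile_rates(ev, min_depth=config.min_depth)
                for cid, ev in events.items()}
    pd.concat([ev.to_frame().assign(captor_id=cid)
               for cid, ev in events.items()]).pipe(
        write_tsv, out / "event_profiles.tsv")

    # per-6-mer error table and pore/time summary
    ktab = kmer_table(profiles, panel)
    write_tsv(ktab, out / "kmer_error_table.tsv")
    binned, per_channel = pore_time_summary(
        class_df.dropna(subset=["per_read_error"]), time_bin=config.time_bin)
    write_tsv(per_channel, out / "pore_summary.tsv")

    # ladder
    counts, n_uncl = captor_counts(class_df)
    fit = ladder_fit(counts, mix)
    ladder = {"slope": fit.slope, "intercept": fit.intercept,
              "r_squared": fit.r_squared, "n_points": fit.n_points,
              "slope_ci_halfwidth": fit.slope_ci_halfwidth,
              "n_unclassified": n_uncl,
              "not_detected": list(fit.not_detected)}
    write_json(ladder, out / "ladder.json")
    manifest["stages"]["ladder"] = ladder
    manifest["artefacts"].update({
        "reads_fastq": "reads.fastq", "truth_tsv": "truth.tsv",
        "classifications_tsv": "classifications.tsv",
        "event_profiles_tsv": "event_profiles.tsv",
        "kmer_error_table_tsv": "kmer_error_table.tsv",
        "pore_summary_tsv": "pore_summary.tsv", "ladder_json": "ladder.json"})
    write_json(manifest, out / "run_manifest.json")
    return manifest
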