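"""Seeded replicate orchestration and file outputs."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ScenarioPreset, SimulationConfig, load_config, preset
from .exports import sample_for_export, write_fasta, write_newick, write_nexus, write_vcf
from .genetics import MT_MARKER, Y_MARKER, drop_mutations, extract_gene_tree
from .population import MALE
from .simulate import ReplicateResult, run_replicate
from .stats import ReplicateSummary, summarize_replicates

_PHASE_OVERRIDE_KEYS = {
    "sigma",
    "fission_type",
    "violence_rate",
    "polygyny",
    "post_fission_migration",
}


def replicate_seeds(base_seed: int, n_replicates: int) -> list[int]:
    """Deterministic per-replicate seeds derived from the base seed."""
    rng = np.random.default_rng(np.random.SeedSequence(base_seed))
    return rng.integers(1, 2**31 - 1, size=n_replicates).tolist()


def apply_overrides(
    scenario: ScenarioPreset, config: SimulationConfig, overrides: dict | None
) -> tuple[ScenarioPreset, SimulationConfig]:
    """Apply user overrides to the base config, and to any phase that
    already pins the same key (so e.g. a sigma override reaches the
    patrilineal phase of a preset that fixes sigma)."""
    if not overrides:
        return scenario, config
    config = config.replace(**overrides)
    new_phases = []
    for phase in scenario.phases:
        merged = dict(phase.overrides)
        for key, value in overrides.items():
            if key in merged and key in _PHASE_OVERRIDE_KEYS:
                merged[key] = value
        new_phases.append(dataclasses.replace(phase, overrides=merged))
    return dataclasses.replace(scenario, phases=tuple(new_phases)), config


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    scenario: str
    config: dict
    n_replicates: int
    base_seed: int
    replicate_seeds: list[int]
    outputs: list[str]
    failed_replicates: list[int]
    version: str
    wall_time_per_replicate: list[float]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def run_scenario(
    name: str,
    n_replicates: int,
    seed: int,
    overrides: dict | None = None,
    out_dir: str | Path | None = None,
    total_generations: int | None = None,
    exports: tuple[str, ...] = (),
    n_boot: int = 10_000,
    collect_results: bool = False,
) -> tuple[RunManifest, ReplicateSummary, pd.DataFrame | None]:
    """Run a named scenario for ``n_replicates`` seeded replicates.

    Writes (when ``out_dir`` is given) the pooled diversity, event-log and
    group-size CSVs, a per-generation summary CSV, a one-row scenario
    summary and the manifest; optional exports write the final-generation
    sample in the requested formats from the first replicate.  Failed
    replicates are logged, excluded from summaries and reported in the
    manifest.  Results depend only on (name, config, seed), not on how the
    work is scheduled.
    """
    scenario = preset(name)
    if total_generations is not None:
        scenario = dataclasses.replace(scenario, total_generations=total_generations)
    config = load_config()
    scenario, config = apply_overrides(scenario, config, overrides)
    seeds = replicate_seeds(seed, n_replicates)

    diversity_parts, event_parts, size_parts = [], [], []
    failed: list[int] = []
    walls: list[float] = []
    first_result: ReplicateResult | None = None
    for i, rep_seed in enumerate(seeds):
        t0 = time.perf_counter()
        try:
            res = run_replicate(
                scenario, config, rep_seed, keep_population=bool(exports) and i == 0
            )
        except Exception as exc:  # noqa: BLE001 - partial failure is reported
            failed.append(i)
            walls.append(time.perf_counter() - t0)
            print(f"replicate {i} (seed {rep_seed}) failed: {exc}")
            continue
        walls.append(time.perf_counter() - t0)
        if first_result is None:
            first_result = res
        for part, df in (
            (diversity_parts, res.diversity),
            (event_parts, res.events),
            (size_parts, res.group_sizes),
        ):
            df = df.copy()
            df.insert(0, "replicate", i)
            part.append(df)
    diversity = pd.concat(diversity_parts, ignore_index=True)
    events = pd.concat(event_parts, ignore_index=True)
    group_sizes = pd.concat(size_parts, ignore_index=True)
    summary = summarize_replicates(diversity, scenario=name, n_boot=n_boot)

    outputs: list[str] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fname, df in (
            ("diversity.csv", diversity),
            ("events.csv", events),
            ("group_sizes.csv", group_sizes),
            ("summary_per_generation.csv", summary.per_generation),
        ):
            df.to_csv(out_dir / fname, index=False)
            outputs.append(fname)
        row = pd.DataFrame(
            [
                {
                    "scenario": name,
                    "n_replicates": summary.n_replicates,
                    "reduction_factor": summary.reduction_factor,
                    "reduction_factor_lo": summary.reduction_factor_ci[0],
                    "reduction_factor_hi": summary.reduction_factor_ci[1],
                    "max_ratio": summary.max_ratio,
                }
            ]
        )
        row.to_csv(out_dir / "scenario_summary.csv", index=False)
        outputs.append("scenario_summary.csv")
        if exports and first_result is not None:
            outputs += export_final_sample(first_result, config, out_dir, exports)
    manifest = RunManifest(
        scenario=name,
        config=config.to_dict(),
        n_replicates=n_replicates,
        base_seed=seed,
        replicate_seeds=seeds,
        outputs=outputs,
        failed_replicates=failed,
        version=__version__,
        wall_time_per_replicate=walls,
    )
    if out_dir is not None:
        manifest.write(Path(out_dir) / "manifest.json")
    return manifest, summary, diversity if collect_results else None


def export_final_sample(
    result: ReplicateResult,
    config: SimulationConfig,
    out_dir: Path,
    formats: tuple[str, ...],
) -> list[str]:
    """Write the final-generation 10M+10F per-village sample.

    The Y files cover the 50 sampled males; the mtDNA files cover all 100
    individuals (everyone carries mtDNA).
    """
    pop = result.population
    rng = np.random.default_rng(np.random.SeedSequence([result.seed, 97]))
    idx, labels = sample_for_export(pop, rng)
    written: list[str] = []
    for marker, mu, length in (
        (Y_MARKER, config.mu_y, config.len_y),
        (MT_MARKER, config.mu_mt, config.len_mt),
    ):
        if marker == Y_MARKER:
            keep = pop.sex[idx] == MALE
        else:
            keep = np.ones(len(idx), dtype=bool)
        sub_idx = idx[keep]
        sub_labels = [l for l, k in zip(labels, keep) if k]
        tree = extract_gene_tree(
            pop.ids[sub_idx],
            pop.pedigree,
            result.burn_in[marker],
            result.founder_tips[marker],
            pop.generation,
            marker,
            sample_sexes=pop.sex[sub_idx] if marker == Y_MARKER else None,
        )
        seqs = drop_mutations(tree, mu, length, rng)
        tag = "Y" if marker == Y_MARKER else "mt"
        full = marker == MT_MARKER  # full sequences are practical at mtDNA scale
        if "fasta" in formats:
            write_fasta(seqs, sub_labels, out_dir / f"sample_{tag}.fasta", full_length=full)
            written.append(f"sample_{tag}.fasta")
        if "newick" in formats:
            write_newick(tree, sub_labels, out_dir / f"sample_{tag}.nwk")
            written.append(f"sample_{tag}.nwk")
        if "nexus" in formats:
            write_nexus(tree, seqs, sub_labels, out_dir / f"sample_{tag}.nex", full_length=full)
            written.append(f"sample_{tag}.nex")
        if "vcf" in formats:
            write_vcf(seqs, sub_labels, out_dir / f"sample_{tag}.vcf", contig=tag)
            written.append(f"sample_{tag}.vcf")
    return written
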