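"""End-to-end orchestration: simulate -> contrasts -> classify -> mutations
-> growth, plus reproduction of the packaged study tables.

Every run is fully determined by its config and seed; all output files carry
a provenance header with the package version, the seed and a hash of the
config so that reruns are byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, contrasts, growth, io, mutations, simulate, trajectories

logger = logging.getLogger(__name__)

#: Loci merged into one functional target when tabulating parallelism.
TARGET_ALIASES = {"atpI": "ATP_synthase", "atpF": "ATP_synthase"}
#: The engineered plasmid counts as a single collective target.
REGION_TARGETS = {"pCM410": "pCM410"}


@dataclass
class RunConfig:
    """Thresholds and generator settings for a full pipeline run."""

    seed: int = 0
    outdir: str = "evomex_run"
    # expression simulation
    n_genes: int = 2000
    n_probes_per_gene: int = 1
    n_replicates: int = 3
    lineages: tuple[str, ...] = tuple(f"F{i}" for i in range(1, 9))
    acclimation_effect: float = 2.0
    adaptation_effect: float = 2.0
    noise_sd: float = 0.25
    category_proportions: dict = field(
        default_factory=lambda: dict(simulate.DEFAULT_PROPORTIONS)
    )
    # thresholds
    q_threshold: float = 0.05
    tau: float = 0.5
    upstream_window: int = 2500
    ancestral_min: int = 6
    min_window: int = 5
    r2_min: float = 0.99
    # mutation simulation
    n_mutations_per_lineage: int = 8
    n_ancestral: int = 2
    # growth simulation
    em_mu: float = 0.08
    growth_noise_cv: float = 0.02
    growth_replicates: int = 3

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # where outputs land does not change what they are
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"evomex {__version__}; seed={config.seed}; config={config.config_hash()}"


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage on synthetic inputs and write the report bundle.

    Outputs in ``config.outdir``: matrix/sample/probe-map TSVs, truth.tsv,
    contrasts.tsv, calls.tsv, sharing.tsv, restoration.tsv, per-lineage .gd
    files, annotated_mutations.tsv, target_matrix.tsv, lineage_summary.tsv,
    rates.tsv, report.txt and manifest.json.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    rng = np.random.default_rng(config.seed)
    stage_seeds = rng.integers(0, 2**31 - 1, size=4)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = time.perf_counter() - timings[name]

    # --- expression ---------------------------------------------------
    _stage("simulate_expression")
    sim_cfg = simulate.SimulationConfig(
        n_genes=config.n_genes,
        n_probes_per_gene=config.n_probes_per_gene,
        n_replicates=config.n_replicates,
        lineages=tuple(config.lineages),
        category_proportions=config.category_proportions,
        acclimation_effect=config.acclimation_effect,
        adaptation_effect=config.adaptation_effect,
        noise_sd=config.noise_sd,
        seed=int(stage_seeds[0]),
    )
    matrix, truth = simulate.simulate_expression(sim_cfg)
    io.write_expression(
        matrix,
        outdir / "matrix.tsv",
        outdir / "samples.csv",
        outdir / "probe_map.tsv",
        provenance=prov,
    )
    io.write_table(truth, outdir / "truth.tsv", provenance=prov, index=False)
    _done("simulate_expression")

    _stage("contrasts")
    table = contrasts.contrast_table(matrix)
    io.write_table(table, outdir / "contrasts.tsv", provenance=prov, index=False)
    _done("contrasts")

    _stage("classify")
    calls = trajectories.classify_table(
        table, q_threshold=config.q_threshold, tau=config.tau
    )
    sharing = trajectories.novel_sharing(calls)
    restoration = trajectories.restoration_summary(calls)
    io.write_table(calls, outdir / "calls.tsv", provenance=prov, index=False)
    io.write_table(sharing, outdir / "sharing.tsv", provenance=prov, index=False)
    io.write_table(restoration, outdir / "restoration.tsv", provenance=prov, index=False)
    _done("classify")

    # --- mutations ------------------------------------------------------
    _stage("mutations")
    mut_cfg = simulate.MutationSimConfig(
        lineages=tuple(config.lineages),
        n_mutations_per_lineage=config.n_mutations_per_lineage,
        n_ancestral=config.n_ancestral,
        seed=int(stage_seeds[1]),
    )
    records, mut_truth = simulate.simulate_mutations(mut_cfg)
    annotation = mut_truth["annotation"]
    gd_dir = outdir / "gd"
    gd_dir.mkdir(exist_ok=True)
    for lineage in config.lineages:
        io.write_genomediff(
            gd_dir / f"{lineage}.gd",
            [r for r in records if r.lineage == lineage],
            provenance=prov,
        )
    io.write_gff3(outdir / "genome.gff3", annotation, provenance=prov)
    filtered = mutations.filter_ancestral(
        mutations.filter_marginal_calls(records), min_shared_lineages=config.ancestral_min
    )
    annotated = mutations.annotate_records(
        filtered, annotation, upstream_window=config.upstream_window
    )
    io.write_table(
        mutations.records_with_targets(annotated),
        outdir / "annotated_mutations.tsv",
        provenance=prov,
        index=False,
    )
    target_matrix = mutations.build_target_matrix(annotated)
    io.write_table(
        target_matrix.replace({True: "+", False: "-"}),
        outdir / "target_matrix.tsv",
        provenance=prov,
    )
    summary = mutations.lineage_summary(annotated)
    io.write_table(summary, outdir / "lineage_summary.tsv", provenance=prov)
    _done("mutations")

    # --- growth ---------------------------------------------------------
    _stage("growth")
    strain_summary = load_strain_summary()
    rel = dict(zip(strain_summary["population"], strain_summary["growth_relative_to_em"]))
    curve_seed_rng = np.random.default_rng(int(stage_seeds[2]))
    times = np.arange(0.0, 60.0, 1.0)
    curves = []
    for strain in ["EM", *config.lineages]:
        mu = config.em_mu * rel.get(strain, 1.0)
        for r in range(1, config.growth_replicates + 1):
            curves.append(
                simulate.simulate_growth_curve(
                    mu=mu,
                    lag=3.0,
                    od0=0.01,
                    od_max=1.0,
                    noise_cv=config.growth_noise_cv,
                    times=times,
                    seed=int(curve_seed_rng.integers(0, 2**31 - 1)),
                    culture_id=f"{strain}_{r}",
                    strain=strain,
                )
            )
    io.write_table(
        growth.curves_to_long_frame(curves), outdir / "curves.csv",
        sep=",", provenance=prov, index=False,
    )
    rates = growth.estimate_rates(curves, min_window=config.min_window, r2_min=config.r2_min)
    per_strain = rates.groupby(rates["strain"])["mu"].mean()
    rel_rows = []
    for strain in config.lineages:
        fold, benefit = growth.relative_rate(per_strain[strain], per_strain["EM"])
        rel_rows.append({"strain": strain, "fold_vs_EM": fold, "benefit": benefit})
    rates_out = rates.merge(
        pd.DataFrame(rel_rows), how="left", left_on="strain", right_on="strain"
    )
    io.write_table(rates_out, outdir / "rates.tsv", provenance=prov, index=False)
    _done("growth")

    # --- report -----------------------------------------------------------
    counts = mutations.parallelism_counts(target_matrix)
    report = [
        f"evomex {__version__} pipeline report",
        f"seed: {config.seed}",
        f"config hash: {config.config_hash()}",
        "",
        "category counts per lineage:",
        restoration.to_string(index=False),
        "",
        "top parallel mutation targets (lineages hit):",
        counts.head(10).to_string(),
        "",
        "mean growth rate per strain (1/h):",
        per_strain.round(4).to_string(),
    ]
    logger.info(
        "stage timings (s): %s", ", ".join(f"{k}={v:.2f}" for k, v in timings.items())
    )
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    output_names = [
        "matrix.tsv", "samples.csv", "probe_map.tsv", "truth.tsv", "contrasts.tsv",
        "calls.tsv", "sharing.tsv", "restoration.tsv", "annotated_mutations.tsv",
        "target_matrix.tsv", "lineage_summary.tsv", "curves.csv", "rates.tsv",
        "report.txt", "manifest.json",
    ]
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "outputs": output_names,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    for name in output_names:
        outputs[name] = outdir / name
    return outputs


# ---------------------------------------------------------------------------
# Packaged study-table fixtures
# ---------------------------------------------------------------------------

def data_path(name: str) -> Path:
    return Path(str(resources.files("evomex") / "data" / name))


def load_strain_summary() -> pd.DataFrame:
    """Published per-lineage summary: growth vs EM, novel-expression counts
    and mutation tallies."""
    return io.read_table(data_path("strain_summary.tsv"))


def load_expected_target_matrix() -> pd.DataFrame:
    return io.read_table(data_path("parallel_targets_expected.tsv"), index_col=0)


def load_rpoa_expression() -> pd.DataFrame:
    """Published expression divergence of the RNA-polymerase-mutant lineages."""
    return io.read_table(data_path("rpoa_expression.tsv"))


def load_fixture_annotation() -> io.GenomeAnnotation:
    return io.read_gff3(data_path("toy_genome.gff3"))


def load_fixture_records(gd_dir: Path | None = None) -> list[io.MutationRecord]:
    gd_dir = gd_dir or data_path("gd")
    records: list[io.MutationRecord] = []
    for path in sorted(Path(gd_dir).glob("*.gd")):
        records.extend(io.read_genomediff(path, lineage=path.stem))
    if not records:
        raise FileNotFoundError(f"no .gd files found in {gd_dir}")
    return records


def fixture_target_matrix(
    gd_dir: Path | None = None,
    upstream_window: int = 2500,
    ancestral_min: int = 6,
) -> pd.DataFrame:
    """Recompute the parallel-target presence matrix from the packaged
    GenomeDiff fixtures (filter -> annotate -> tabulate)."""
    records = load_fixture_records(gd_dir)
    annotation = load_fixture_annotation()
    filtered = mutations.filter_ancestral(
        mutations.filter_marginal_calls(records), min_shared_lineages=ancestral_min
    )
    annotated = mutations.annotate_records(
        filtered,
        annotation,
        upstream_window=upstream_window,
        region_targets=REGION_TARGETS,
    )
    return mutations.build_target_matrix(annotated, target_aliases=TARGET_ALIASES)


def fixture_trajectory_calls(q_threshold: float = 0.05, tau: float = 0.5) -> pd.DataFrame:
    """Classify the packaged contrast fixture for the RNAP-mutant lineages."""
    table = io.read_table(data_path("rpoa_contrasts.tsv"))
    table["lineage"] = table["lineage"].fillna("")
    return trajectories.classify_table(table, q_threshold=q_threshold, tau=tau)


def reproduce_tables(gd_dir: Path | None = None) -> dict:
    """Recompute the packaged study tables and diff them against the
    packaged expected renderings.

    Returns a dict with the recomputed target matrix (as +/- strings), the
    recomputed trajectory calls, a ``match`` flag and a human-readable
    ``diff`` string (empty when everything matches).
    """
    diffs: list[str] = []
    computed = fixture_target_matrix(gd_dir).replace({True: "+", False: "-"})
    expected = load_expected_target_matrix()
    computed = computed.sort_index()
    expected = expected.sort_index()
    if not computed.equals(expected):
        diffs.append("target matrix mismatch:")
        diffs.append(f"expected:\n{expected.to_string()}")
        diffs.append(f"computed:\n{computed.to_string()}")

    calls = fixture_trajectory_calls()
    expected_calls = io.read_table(data_path("rpoa_expected_calls.tsv"))
    merged = expected_calls.merge(
        calls[["locus", "lineage", "category"]],
        on=["locus", "lineage"],
        how="left",
        suffixes=("_expected", "_computed"),
    )
    bad = merged[merged["category_expected"] != merged["category_computed"]]
    if not bad.empty:
        diffs.append("trajectory call mismatch:")
        diffs.append(bad.to_string(index=False))
    return {
        "target_matrix": computed,
        "calls": calls,
        "match": not diffs,
        "diff": "\n".join(diffs),
    }
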