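"""End-to-end orchestration: simulate/ingest -> filter -> stats -> structure
-> tree/PCA -> core collection -> fingerprint.

Every stage writes standard text artifacts (VCF, TSV, Newick, JSON) into
the output directory, and ``run_all`` finishes with a manifest recording
per-stage seeds, record counts and SHA-256 checksums of every output.
Stage seeds derive from the master seed by hashing the stage name, so a
stage is reproducible on its own and insensitive to reordering of the
others.  Timings go to ``run.log``, not the manifest, keeping re-runs of
the same configuration byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import delta_k_from_fits, run_k_grid, structure_report
from .corebank import DEFAULT_RATIOS, build_core, recommend_ratio, sweep_ratios
from .divstats import locus_table, population_summary, round_report
from .fingerprint import build_fingerprint, heatmap_matrix
from .genotype_io import (
    GenotypePanel,
    filter_samples,
    filter_variants,
    read_vcf,
    write_vcf,
)
from .popstruct import assign_groups, ibs_distance, neighbor_joining, pca, to_newick
from .syndata import SimulationConfig, simulate_panel, write_truth


@dataclass
class RunConfig:
    """One analysis run: exactly one of ``vcf`` / ``simulation`` as input."""

    vcf: str | None = None
    simulation: SimulationConfig | None = None
    max_sample_missing: float = 0.999
    min_depth: int = 20
    max_locus_missing: float = 0.10
    min_af: float = 0.05
    k_min: int = 1
    k_max: int = 5
    n_replicates: int = 5
    n_groups: int = 2
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    fingerprint_n: int = 20
    seed: int = 0
    outdir: str = "hevecore_run"

    def __post_init__(self) -> None:
        if (self.vcf is None) == (self.simulation is None):
            raise ValueError("specify exactly one of vcf / simulation")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed and stage name."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.seed,
        "stages": [],
    }

    def record(stage: str, outputs: list[Path], seed: int | None, t0: float,
               **counts) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "seed": seed,
                "outputs": [
                    {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                    for p in outputs
                ],
                **counts,
            }
        )
        log_lines.append(f"{stage}\t{time.time() - t0:.2f}s\t{counts}")

    current_stage = "input"
    try:
        # ---- input ------------------------------------------------------
        t0 = time.time()
        if config.simulation is not None:
            sim = config.simulation
            panel, truth = simulate_panel(sim)
            vcf_path = outdir / "panel.vcf"
            write_vcf(panel, vcf_path)
            truth_dir = outdir / "truth"
            write_truth(truth, truth_dir)
            outputs = [vcf_path, truth_dir / "samples.tsv", truth_dir / "frequencies.tsv"]
            record("input", outputs, sim.seed, t0,
                   n_samples=panel.n_samples, n_loci=panel.n_loci)
        else:
            panel = read_vcf(config.vcf)
            manifest["input_sha256"] = _sha256(Path(config.vcf))
            record("input", [], None, t0,
                   n_samples=panel.n_samples, n_loci=panel.n_loci)

        # ---- sample / variant filters -----------------------------------
        current_stage = "filter_samples"
        t0 = time.time()
        panel, srep = filter_samples(panel, config.max_sample_missing)
        p = outdir / "filter_samples.json"
        srep.to_json(p)
        record("filter_samples", [p], None, t0,
               n_in=srep.n_samples_in, n_out=srep.n_samples_out)

        current_stage = "filter_variants"
        t0 = time.time()
        min_depth = config.min_depth if panel.DP is not None else 0
        panel, vrep = filter_variants(
            panel, min_depth, config.max_locus_missing, config.min_af
        )
        vcf_path = outdir / "filtered.vcf"
        write_vcf(panel, vcf_path)
        p = outdir / "filter_variants.json"
        vrep.to_json(p)
        record("filter_variants", [vcf_path, p], None, t0,
               n_in=vrep.n_loci_in, n_out=vrep.n_loci_out)

        # ---- per-locus statistics ---------------------------------------
        current_stage = "stats"
        t0 = time.time()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats = locus_table(panel)
        p = outdir / "locus_stats.tsv"
        round_report(stats).to_csv(p, sep="\t", index=False)
        record("stats", [p], None, t0, n_loci=len(stats))

        # ---- tree, groups, PCA ------------------------------------------
        current_stage = "tree"
        t0 = time.time()
        dm = ibs_distance(panel)
        tree = neighbor_joining(dm)
        newick_path = outdir / "nj_tree.nwk"
        newick_path.write_text(to_newick(tree) + "\n")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            label_map = assign_groups(tree, k=config.n_groups)
        labels = np.array([label_map[s] for s in panel.sample_ids])
        groups_path = outdir / "groups.tsv"
        pd.DataFrame({"sample": panel.sample_ids, "group": labels}).to_csv(
            groups_path, sep="\t", index=False
        )
        pca_res = pca(panel, n_components=min(10, panel.n_samples - 1))
        pca_path = outdir / "pca.tsv"
        coords = pd.DataFrame(
            pca_res.coordinates,
            columns=[f"PC{c + 1}" for c in range(pca_res.coordinates.shape[1])],
        )
        coords.insert(0, "sample", pca_res.sample_ids)
        coords.to_csv(pca_path, sep="\t", index=False, float_format="%.6g")
        ev_path = outdir / "pca_explained.tsv"
        pd.DataFrame(
            {
                "component": [f"PC{c + 1}" for c in range(len(pca_res.explained_pct))],
                "explained_pct": np.round(pca_res.explained_pct, 4),
            }
        ).to_csv(ev_path, sep="\t", index=False)
        record("tree", [newick_path, groups_path, pca_path, ev_path], None, t0,
               n_groups=int(len(set(labels))))

        # ---- population summaries ---------------------------------------
        current_stage = "summary"
        t0 = time.time()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = population_summary(panel, labels)
        p = outdir / "population_summary.tsv"
        round_report(summary).to_csv(p, sep="\t", index=False)
        record("summary", [p], None, t0, n_groups=len(summary))

        # ---- admixture + Evanno ΔK --------------------------------------
        current_stage = "structure"
        t0 = time.time()
        seed = stage_seed(config.seed, "structure")
        fits = run_k_grid(
            panel,
            k_min=config.k_min,
            k_max=config.k_max,
            n_replicates=config.n_replicates,
            seed=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dk = delta_k_from_fits(fits)
        best_k = dk.attrs["best_k"]
        dk_path = outdir / "delta_k.tsv"
        dk.round(6).to_csv(dk_path, sep="\t", index=False)
        report_k = best_k if best_k in fits else config.n_groups
        if report_k not in fits:
            report_k = max(fits)
        best_fit = max(fits[report_k], key=lambda f: f.loglik)
        q_path = outdir / "qmatrix.tsv"
        structure_report(best_fit, panel.sample_ids).round(6).to_csv(
            q_path, sep="\t", index=False
        )
        record("structure", [dk_path, q_path], seed, t0, best_k=best_k)

        # ---- core collection --------------------------------------------
        current_stage = "core"
        t0 = time.time()
        sweep = sweep_ratios(panel, labels, config.ratios)
        sweep_path = outdir / "core_sweep.tsv"
        round_report(sweep).to_csv(sweep_path, sep="\t", index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratio = recommend_ratio(sweep)
        core = build_core(panel, labels, ratio)
        ids_path = outdir / "core_ids.txt"
        ids_path.write_text("\n".join(core.sample_ids) + "\n")
        rec_path = outdir / "core_recommendation.json"
        rec_path.write_text(
            json.dumps(
                {
                    "recommended_ratio": ratio,
                    "n_core": len(core.sample_ids),
                    "n_total": panel.n_samples,
                    "core_pct_of_total": round(
                        100.0 * len(core.sample_ids) / panel.n_samples, 2
                    ),
                },
                indent=2,
            )
            + "\n"
        )
        record("core", [sweep_path, ids_path, rec_path], None, t0,
               n_core=len(core.sample_ids))

        # ---- fingerprint ------------------------------------------------
        current_stage = "fingerprint"
        t0 = time.time()
        fp = build_fingerprint(panel, n_max=config.fingerprint_n)
        codes_path = outdir / "fingerprint_codes.tsv"
        fp.codes.rename("code").to_frame().to_csv(codes_path, sep="\t")
        payload_path = outdir / "fingerprint_payloads.txt"
        payload_path.write_text("\n".join(fp.qr_payloads()) + "\n")
        hm_path = outdir / "fingerprint_heatmap.tsv"
        heatmap_matrix(panel, fp.locus_ids).to_csv(hm_path, sep="\t")
        record("fingerprint", [codes_path, payload_path, hm_path], None, t0,
               n_loci=len(fp.locus_ids), n_unresolved_pairs=fp.n_unresolved_pairs)
    except Exception as exc:
        (outdir / "run.log").write_text(
            "\n".join(log_lines + [f"FAILED at stage {current_stage}: {exc}"]) + "\n"
        )
        raise RuntimeError(f"pipeline failed at stage '{current_stage}': {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a plain (e.g. JSON-loaded) dictionary."""
    d = dict(d)
    sim = d.get("simulation")
    if isinstance(sim, dict):
        sim = dict(sim)
        if "n_samples_per_pop" in sim:
            sim["n_samples_per_pop"] = tuple(sim["n_samples_per_pop"])
        d["simulation"] = SimulationConfig(**sim)
    if "ratios" in d and d["ratios"] is not None:
        d["ratios"] = tuple(d["ratios"])
    return RunConfig(**d)


def config_to_dict(config: RunConfig) -> dict:
    out = asdict(config)
    return out
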