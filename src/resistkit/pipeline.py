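"""End-to-end orchestration: synth -> de -> cascade, plus kdr and qpcr.

A run is a pure function of (RunConfig, input files): every seed and
threshold is recorded in the emitted ``manifest.json`` together with the
SHA-256 of every output file, so a run is reproducible from manifest +
inputs and identical configurations produce identical manifests.  Stages
whose configuration and upstream outputs are unchanged are skipped on
rerun (their fingerprints match the existing manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .cascade import CascadeConfig, cluster_candidates, run_cascade
from .de import contrast_label, fit_contrasts, normalize
from .design import vk_design_2011, vk_design_2012
from .kdr import (
    AlleleCountRow,
    allele_frequency,
    em_haplotype_frequencies,
    fisher_survival_test,
    haplotype_association,
)
from .qpcr import relative_expression, year_comparison
from .synth import (
    GenotypeSimParams,
    make_expression_truth,
    simulate_genotypes,
    simulate_qpcr,
    simulate_two_color_experiment,
)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("synth", "de", "cascade", "kdr", "qpcr")


@dataclass
class RunConfig:
    """Flat, fully explicit configuration of a pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    # synth / de
    n_probes: int = 1000
    n_replicates_per_edge: int = 3
    noise_sd: float = 0.25
    dye_bias: float = 0.1
    array_effect_sd: float = 0.2
    normalization: str = "median"
    dye_effect: bool = True
    epsilon: float = 1.0
    # cascade
    q_threshold: float = 0.05
    significance_mode: str = "all"
    linkage: str = "average"
    step_d_enabled: bool = True
    # kdr
    haplotype_freqs: dict = field(
        default_factory=lambda: {"L-N": 0.15, "F-N": 0.55, "F-Y": 0.30}
    )
    survival_or_fy: float = 2.7
    n_per_arm: int = 500
    ci_method: str = "clopper_pearson"
    conf: float = 0.95
    em_tol: float = 1e-8
    em_mode: str = "pooled"
    # qpcr
    qpcr_levels: dict = field(
        default_factory=lambda: {"VK7_2011": 1.0, "VK7_2012": 3.0, "VK7_2013": 5.0}
    )
    qpcr_efficiency: float = 1.95
    qpcr_n_replicates: int = 6
    qpcr_noise_sd: float = 0.15
    calibrator: str = "VK7_2011"
    ttest_variant: str = "welch"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.calibrator not in self.qpcr_levels:
            raise ValueError(
                f"calibrator {self.calibrator!r} absent from qpcr_levels"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fingerprint(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Execute the configured stages in dependency order under ``out_dir``.

    Returns the manifest (also written to ``manifest.json``): the full
    configuration, per-stage output paths with SHA-256 hashes, stage
    fingerprints, and the probe counts surviving each cascade filter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    old = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    cfg = config.to_dict()

    def stage_done(name: str, fp: str) -> bool:
        rec = old.get("stages", {}).get(name)
        if force or not rec or rec.get("fingerprint") != fp:
            return False
        return all(
            (out / f).exists() and _sha256(out / f) == h
            for f, h in rec["outputs"].items()
        )

    def record(name: str, fp: str, files: list[Path], extra: dict | None = None) -> None:
        manifest["stages"][name] = {
            "fingerprint": fp,
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
            **(extra or {}),
        }

    upstream_fp = ""

    # ---- synth ----------------------------------------------------------
    if "synth" in config.stages:
        keys = (
            "seed n_probes n_replicates_per_edge noise_sd dye_bias "
            "array_effect_sd haplotype_freqs survival_or_fy n_per_arm "
            "qpcr_levels qpcr_efficiency qpcr_n_replicates qpcr_noise_sd"
        ).split()
        fp = _fingerprint({k: cfg[k] for k in keys})
        files = [
            out / f
            for f in (
                "truth.tsv",
                "design_2011.tsv",
                "design_2012.tsv",
                "intensities_2011.tsv",
                "intensities_2012.tsv",
                "probe_gene_map.tsv",
                "genotypes.csv",
                "qpcr_plate.csv",
            )
        ]
        if not stage_done("synth", fp):
            truth = make_expression_truth(config.n_probes, seed=config.seed)
            d11 = vk_design_2011(config.n_replicates_per_edge)
            d12 = vk_design_2012(config.n_replicates_per_edge)
            i11 = simulate_two_color_experiment(
                d11, truth, config.noise_sd, config.dye_bias,
                config.array_effect_sd, seed=config.seed + 1,
            )
            i12 = simulate_two_color_experiment(
                d12, truth, config.noise_sd, config.dye_bias,
                config.array_effect_sd, seed=config.seed + 2,
            )
            geno = simulate_genotypes(
                GenotypeSimParams(
                    haplotype_freqs=config.haplotype_freqs,
                    survival_odds_ratio_per_haplotype={"F-Y": config.survival_or_fy},
                    n_per_arm=config.n_per_arm,
                    seed=config.seed + 3,
                )
            )
            plate = simulate_qpcr(
                config.qpcr_levels,
                efficiencies={"GSTE2": config.qpcr_efficiency},
                n_replicates=config.qpcr_n_replicates,
                noise_sd=config.qpcr_noise_sd,
                seed=config.seed + 4,
            )
            truth.to_csv(files[0], sep="\t", index=False)
            rio.write_design(d11, files[1])
            rio.write_design(d12, files[2])
            rio.write_intensities(i11, files[3])
            rio.write_intensities(i12, files[4])
            rio.write_probe_gene_map(truth[["probe_id", "gene_id"]], files[5])
            rio.write_genotypes(geno, files[6])
            rio.write_plate(plate, files[7])
        record("synth", fp, files)
        upstream_fp = fp

    # ---- de -------------------------------------------------------------
    if "de" in config.stages:
        keys = "normalization dye_effect epsilon".split()
        fp = _fingerprint({k: cfg[k] for k in keys} | {"upstream": upstream_fp})
        files = [out / "contrasts.tsv"]
        if not stage_done("de", fp):
            d11 = rio.read_design(out / "design_2011.tsv")
            d12 = rio.read_design(out / "design_2012.tsv")
            i11 = rio.read_intensities(out / "intensities_2011.tsv")
            i12 = rio.read_intensities(out / "intensities_2012.tsv")
            n11 = normalize(i11, method=config.normalization, epsilon=config.epsilon)
            n12 = normalize(i12, method=config.normalization, epsilon=config.epsilon)
            c11 = fit_contrasts(
                n11, d11,
                [("VKR2011", "MAL2011"), ("VKC2011", "MAL2011"), ("VKR2011", "VKC2011")],
                dye_effect=config.dye_effect,
            )
            c12 = fit_contrasts(
                n12, d12,
                [
                    ("VKR2012", "MAL2012"),
                    ("VKR2012", "NG2012"),
                    ("VKR2012", "TEN2012"),
                    ("TEN2012", "MAL2012"),
                ],
                dye_effect=config.dye_effect,
            )
            merged = pd.concat([c11, c12], ignore_index=True)
            rio.write_contrasts(merged, files[0])
        record("de", fp, files)
        upstream_fp = fp

    # ---- cascade --------------------------------------------------------
    if "cascade" in config.stages:
        keys = "q_threshold significance_mode linkage step_d_enabled".split()
        fp = _fingerprint({k: cfg[k] for k in keys} | {"upstream": upstream_fp})
        files = [
            out / f
            for f in (
                "cascade_steps.tsv",
                "candidate_genes.tsv",
                "down_regulated_genes.tsv",
                "cluster_leaves.tsv",
                "cluster.nwk",
            )
        ]
        counts: dict[str, int] = {}
        if not stage_done("cascade", fp) or "counts" not in old.get("stages", {}).get(
            "cascade", {}
        ):
            contrasts = rio.read_contrasts(out / "contrasts.tsv")
            pg_map = rio.read_probe_gene_map(out / "probe_gene_map.tsv")
            ccfg = CascadeConfig(
                q_threshold=config.q_threshold,
                significance_mode=config.significance_mode,
                linkage=config.linkage,
            )
            if not config.step_d_enabled:
                present = set(contrasts["contrast"])
                if ccfg.vk7_vs_ten_contrast not in present:
                    raise ValueError(
                        "step D enabled but contrast "
                        f"{ccfg.vk7_vs_ten_contrast!r} is missing"
                    )
            result = run_cascade(contrasts, ccfg, pg_map)
            steps = pd.DataFrame(
                [
                    (step, probe)
                    for step, probes in result.surviving_probes_per_step.items()
                    for probe in sorted(probes)
                ],
                columns=["step", "probe_id"],
            )
            steps.to_csv(files[0], sep="\t", index=False)
            result.candidate_genes.to_csv(files[1], sep="\t", index=False)
            result.down_regulated_genes.to_csv(files[2], sep="\t", index=False)
            prof = (
                contrasts[
                    contrasts["contrast"].isin(
                        [
                            contrast_label("VKR2011", "MAL2011"),
                            contrast_label("VKR2012", "MAL2012"),
                            contrast_label("VKR2012", "NG2012"),
                        ]
                    )
                    & contrasts["probe_id"].isin(result.candidate_probes)
                ]
                .pivot_table(index="probe_id", columns="contrast", values="log2FC")
            )
            clus = cluster_candidates(prof, linkage=config.linkage)
            pd.DataFrame({"probe_id": clus["leaves"]}).to_csv(
                files[3], sep="\t", index=False
            )
            (out / "cluster.nwk").write_text(clus["newick"] + "\n")
            counts = result.step_counts | {
                "candidate_genes": len(result.candidate_genes),
                "down_regulated_probes": len(result.down_regulated_probes),
                "down_regulated_genes": len(result.down_regulated_genes),
            }
        else:
            counts = old["stages"]["cascade"].get("counts", {})
        record("cascade", fp, files, {"counts": counts})

    # ---- kdr ------------------------------------------------------------
    if "kdr" in config.stages:
        keys = "ci_method conf em_tol em_mode".split()
        fp = _fingerprint(
            {k: cfg[k] for k in keys}
            | {"upstream": manifest["stages"].get("synth", {}).get("fingerprint", "")}
        )
        files = [out / "kdr_frequencies.tsv", out / "kdr_haplotypes.tsv"]
        if not stage_done("kdr", fp):
            geno = rio.read_genotypes(out / "genotypes.csv")
            freq_rows = []
            for (site, rnd, status), grp in geno.groupby(["site", "round", "status"]):
                for locus, col, mut in (
                    ("L1014F", "genotype_1014", "F"),
                    ("N1575Y", "genotype_1575", "Y"),
                ):
                    alleles = "".join(grp[col])
                    row = AlleleCountRow(
                        site, rnd, status, locus,
                        count_wildtype=alleles.count("L" if mut == "F" else "N"),
                        count_mutant=alleles.count(mut),
                    )
                    fr = allele_frequency(row, config.ci_method, config.conf)
                    freq_rows.append(
                        (site, rnd, status, locus, row.count_wildtype,
                         row.count_mutant, fr.f, fr.ci_low, fr.ci_high)
                    )
            pd.DataFrame(
                freq_rows,
                columns=["site", "round", "status", "locus", "count_wildtype",
                         "count_mutant", "f", "ci_low", "ci_high"],
            ).to_csv(files[0], sep="\t", index=False)
            fit = em_haplotype_frequencies(geno, tol=config.em_tol)
            assoc = haplotype_association(geno, em_mode=config.em_mode)
            assoc.insert(
                0, "pooled_freq", [fit.frequencies[h] for h in assoc["haplotype"]]
            )
            header = "# " + assoc.attrs["orientation"] + "\n"
            with open(files[1], "w") as fh:
                fh.write(header)
                assoc.to_csv(fh, sep="\t", index=False)
        record("kdr", fp, files)

    # ---- qpcr -----------------------------------------------------------
    if "qpcr" in config.stages:
        keys = "calibrator ttest_variant".split()
        fp = _fingerprint(
            {k: cfg[k] for k in keys}
            | {"upstream": manifest["stages"].get("synth", {}).get("fingerprint", "")}
        )
        files = [out / "qpcr_relative_expression.tsv", out / "qpcr_year_tests.tsv"]
        if not stage_done("qpcr", fp):
            plate = rio.read_plate(out / "qpcr_plate.csv")
            res = relative_expression(plate, calibrator=config.calibrator)
            res["summary"].to_csv(files[0], sep="\t", index=False)
            pops = sorted(plate["population_year"].unique())
            tests = []
            for gene in res["summary"]["gene"].unique():
                for a, b in zip(pops, pops[1:]):
                    t, p = year_comparison(res, gene, b, a, config.ttest_variant)
                    tests.append((gene, a, b, t, p))
            pd.DataFrame(
                tests, columns=["gene", "year_a", "year_b", "t", "p"]
            ).to_csv(files[1], sep="\t", index=False)
        record("qpcr", fp, files)

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
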