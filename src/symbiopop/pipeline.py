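"""End-to-end orchestration: simulate/load -> SNPs -> F_ST/ANI -> tests -> ordination.

A run is described by a :class:`RunConfig` (YAML round-trippable; every
random procedure gets an explicit seed derived from the master seed) and
produces a fixed set of text artifacts plus ``manifest.json`` recording
package versions, seeds, input digests and per-stage wall time.  Reruns of
the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import host_genetics, io as spio, ordination, popgen, stats, variants
from .datatypes import Dataset, ValidationError
from .simulate import scenario_library, simulate_dataset, read_fixture

log = logging.getLogger("symbiopop")

ARTIFACTS = ("ani_matrix.tsv", "fst_matrix.tsv", "gene_fst.tsv", "mantel.json",
             "gene_tests.tsv", "nmds_coordinates.tsv", "varpart.json",
             "varpart.tsv")


@dataclass
class RunConfig:
    """Flat, per-module configuration of one pipeline run."""

    scenario: str | None = "paper_null"
    input_dir: str | None = None
    outdir: str = "symbiopop_run"
    seed: int = 0
    # variants
    min_depth: int = variants.DEFAULT_MIN_DEPTH
    min_maf: float = variants.DEFAULT_MIN_MAF
    min_sample_fraction: float = variants.DEFAULT_MIN_SAMPLE_FRACTION
    # association_stats
    mantel_n_perm: int = 9999
    mantel_tail: str = "greater"
    clr_n_mc: int = 128
    alpha: float = 0.05
    # ordination
    rda_n_perm: int = 1000
    nmds_k: int = 2
    nmds_restarts: int = 4

    def validate(self) -> "RunConfig":
        if (self.scenario is None) == (self.input_dir is None):
            raise ValidationError(
                "config: exactly one of scenario / input_dir must be set")
        if self.seed < 0 or self.seed >= 2 ** 31:
            raise ValidationError("seed: must be in [0, 2^31)")
        return self

    def stage_seed(self, offset: int) -> int:
        return (self.seed + offset) % (2 ** 31)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# symbiopop run configuration\n")
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        return cls(**doc).validate()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_dataset(cfg: RunConfig) -> Dataset:
    if cfg.scenario is not None:
        sim = scenario_library(cfg.scenario)
        sim.mc_seed = cfg.seed
        return simulate_dataset(sim)
    return read_fixture(cfg.input_dir)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the artifact bundle; returns the manifest."""
    cfg = config.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(cfg),
                      "stages": {}, "digests": {}, "warnings": []}
    t_all = time.perf_counter()

    def stage(name: str):
        log.info("stage %s", name)
        return _Stage(name, manifest)

    try:
        with stage("load"):
            dataset = _load_dataset(cfg)
        with stage("variants"):
            freqs = variants.call_snps(dataset.counts, cfg.min_depth,
                                       cfg.min_maf, cfg.min_sample_fraction)
            consensus = variants.consensus_alleles(freqs)
        with stage("popgen"):
            fst = popgen.pairwise_fst_matrix(freqs)
            ani = popgen.pairwise_ani(consensus, dataset.gene_catalogue)
            spio.write_distance_matrix(fst.matrix, out / "fst_matrix.tsv")
            ani.ani.to_csv(out / "ani_matrix.tsv", sep="\t",
                           index_label="sample_id", lineterminator="\n")
            fst.gene_table.to_csv(out / "gene_fst.tsv", sep="\t", index=False,
                                  lineterminator="\n")
        with stage("host_genetics"):
            host_d = host_genetics.host_distance(dataset.host_genotypes)
            year_d = host_genetics.year_distance(dataset.metadata)
        with stage("mantel"):
            pairs = {"ani_vs_host": (ani.distance, host_d),
                     "ani_vs_year": (ani.distance, year_d),
                     "fst_vs_host": (fst.matrix, host_d),
                     "fst_vs_year": (fst.matrix, year_d)}
            mantel_out = {}
            for i, (name, (da, db)) in enumerate(pairs.items()):
                res = stats.mantel(da, db, n_perm=cfg.mantel_n_perm,
                                   seed=cfg.stage_seed(10 + i),
                                   tail=cfg.mantel_tail)
                mantel_out[name] = res.as_dict()
            (out / "mantel.json").write_text(
                json.dumps(mantel_out, indent=2, sort_keys=True) + "\n")
        with stage("gene_tests"):
            classes = dataset.metadata["host_class"]
            tables = []
            t = stats.fst_between_within_test(fst.gene_table, classes,
                                              alpha=cfg.alpha)
            t.insert(0, "test", "fst_mannwhitney")
            tables.append(t)
            t = stats.clr_diff_abundance(dataset.coverage, classes,
                                         n_mc=cfg.clr_n_mc,
                                         seed=cfg.stage_seed(20),
                                         alpha=cfg.alpha)
            t.insert(0, "test", "clr_abundance")
            tables.append(t)
            t = stats.presence_absence_test(dataset.coverage > 0, classes,
                                            alpha=cfg.alpha)
            t.insert(0, "test", "presence_absence")
            tables.append(t)
            pd.concat(tables, ignore_index=True).to_csv(
                out / "gene_tests.tsv", sep="\t", index=False,
                lineterminator="\n")
        with stage("ordination"):
            from scipy.spatial.distance import pdist, squareform
            from skbio import DistanceMatrix
            freq_dist = DistanceMatrix(
                squareform(pdist(ordination.impute_frequencies(freqs))),
                ids=list(freqs.samples))
            res_nmds = ordination.nmds(freq_dist, k=cfg.nmds_k,
                                       n_restarts=cfg.nmds_restarts,
                                       seed=cfg.stage_seed(30))
            coords = res_nmds.coordinates.copy()
            coords.insert(0, "stress", res_nmds.stress)
            coords.reset_index(names="sample_id").to_csv(
                out / "nmds_coordinates.tsv", sep="\t", index=False,
                lineterminator="\n")
            blocks = ordination.build_predictors(dataset.metadata)
            testable, aliased = ordination.drop_aliased_blocks(
                blocks.testable_blocks())
            if aliased:
                manifest["warnings"].append(
                    "blocks fully aliased by earlier predictors, excluded "
                    "from varpart: " + ", ".join(aliased))
            if len(testable) >= 2:
                vp = ordination.varpart4(freqs, testable,
                                         n_perm=cfg.rda_n_perm,
                                         seed=cfg.stage_seed(31))
                doc = vp.as_dict()
                doc["non_testable_blocks"] = blocks.non_testable
                doc["collinear_pairs"] = [list(map(str, p[:2])) + [p[2]]
                                          for p in blocks.collinear_pairs]
                vp.to_frame().to_csv(out / "varpart.tsv", sep="\t",
                                     index=False, lineterminator="\n")
            else:
                doc = {"skipped": "fewer than 2 testable predictor blocks",
                       "non_testable_blocks": blocks.non_testable}
                pd.DataFrame(columns=["fraction", "adj_r2", "perm_p"]).to_csv(
                    out / "varpart.tsv", sep="\t", index=False,
                    lineterminator="\n")
                manifest["warnings"].append(doc["skipped"])
            (out / "varpart.json").write_text(
                json.dumps(doc, indent=2, sort_keys=True) + "\n")
            if blocks.collinear_pairs:
                manifest["warnings"].append(
                    "highly collinear predictors: "
                    + ", ".join(f"{a}~{b} (r={r:.2f})"
                                for a, b, r in blocks.collinear_pairs))
    except Exception as exc:
        failed = manifest["stages"].get("_current", "unknown")
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    for name in ARTIFACTS:
        p = out / name
        if p.exists():
            manifest["digests"][name] = _sha256(p)
    manifest["wall_time_s"] = round(time.perf_counter() - t_all, 3)
    manifest["stages"].pop("_current", None)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


class _Stage:
    def __init__(self, name: str, manifest: dict):
        self.name, self.manifest = name, manifest

    def __enter__(self):
        self.manifest["stages"]["_current"] = self.name
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            self.manifest["stages"][self.name] = {
                "wall_time_s": round(time.perf_counter() - self.t0, 3)}
        return False


# ------------------------------------------------------------- validation

@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_inputs(directory: str | Path) -> ValidationReport:
    """Cross-check the tables of a fixture directory; never raises."""
    d = Path(directory)
    report = ValidationReport()
    tables = {}
    readers = {"allele_counts.tsv": spio.read_allele_tsv,
               "gene_catalogue.tsv": spio.read_gene_catalogue,
               "gene_coverage.tsv": spio.read_coverage,
               "metadata.tsv": spio.read_metadata,
               "host_genotypes.tsv": spio.read_host_genotypes}
    for fname, reader in readers.items():
        path = d / fname
        if not path.exists():
            report.issues.append(f"{fname}: missing file")
            continue
        try:
            tables[fname] = reader(path)
        except Exception as exc:
            report.issues.append(f"{fname}: unreadable ({exc})")
    if "allele_counts.tsv" not in tables:
        return report

    counts = tables["allele_counts.tsv"]
    ref = set(counts.samples)
    for fname in ("gene_coverage.tsv", "metadata.tsv", "host_genotypes.tsv"):
        if fname not in tables:
            continue
        got = set(tables[fname].index.astype(str))
        for orphan in sorted(ref - got):
            report.issues.append(f"{fname}: sample {orphan} missing")
        for orphan in sorted(got - ref):
            report.issues.append(f"{fname}: extra sample {orphan}")
    if "gene_catalogue.tsv" in tables:
        genes = set(tables["gene_catalogue.tsv"]["gene_id"].astype(str))
        bad = set(counts.sites["gene_id"].astype(str)) - genes
        for g in sorted(bad):
            report.issues.append(f"allele_counts.tsv: gene {g} not in catalogue")
        if "gene_coverage.tsv" in tables:
            bad = set(map(str, tables["gene_coverage.tsv"].columns)) - genes
            for g in sorted(bad):
                report.issues.append(
                    f"gene_coverage.tsv: gene {g} not in catalogue")
    return report
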