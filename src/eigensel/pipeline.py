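"""Configuration-driven end-to-end pipeline.

Runs QC -> marker diversity -> windowed pi / Tajima's D -> structure
(kinship, GRM, PCA, Rogers distance, NJ tree) -> differentiation (per-SNP
and pairwise F_ST, AMOVA) -> LD decay -> EigenGWAS scan -> selection-region
merging, writing every table as TSV (metadata lines prefixed '#') plus a
run manifest with a config hash and per-file checksums so reruns are
verifiable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity, eigengwas, fst, ld, relatedness, windows
from .errors import InputError
from .io import qc_filter, read_vcf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; loadable from YAML."""

    vcf: str = ""
    metadata: str = ""
    out_dir: str = "eigensel_out"
    max_missing: float = 0.50
    min_maf: float = 0.05
    max_het: float = 0.20
    window: int = 1_000_000
    step: int = 100_000
    by_subpop: bool = True
    ld_max_distance_bp: int = 50_000_000
    ld_threshold: float = 0.1
    n_evs: int = 10
    cutoff: float = 5.0
    flank_bp: int = 5_000_000
    n_perm_fst: int = 0
    n_perm_amova: int = 1000
    n_perm_threshold: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for fld in ("vcf", "metadata"):
            path = getattr(self, fld)
            if not path:
                raise InputError(f"config field {fld!r} is required")
            if not Path(path).exists():
                raise InputError(f"config field {fld!r}: no such file {path!r}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run manifest (also written to disk).

    Any stage failure aborts with a stage-attributed error; tables already
    written are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}

    def emit(name: str, df: pd.DataFrame, meta: dict | None = None):
        path = out / name
        _write_tsv(df, path, meta)
        written.append(path)

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s", name)

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise InputError(f"stage {name!r} failed: {exc}") from exc

        return _Timer()

    with stage("qc"):
        matrix = read_vcf(config.vcf, config.metadata)
        matrix, report = qc_filter(
            matrix,
            max_missing=config.max_missing,
            min_maf=config.min_maf,
            max_het=config.max_het,
        )
        emit("qc_report.tsv", report.to_frame())

    with stage("diversity"):
        emit("marker_stats.tsv", diversity.marker_stats(matrix))
        emit("chromosome_summary.tsv", diversity.grouped_summary(matrix, by="chromosome"))
        emit("genome_summary.tsv", diversity.grouped_summary(matrix, by="genome"))
        emit("subpopulation_summary.tsv", diversity.grouped_summary(matrix, by="subpopulation"))
        emit(
            "substitution_summary.tsv",
            diversity.substitution_summary(matrix.variants).to_frame(),
        )

    with stage("windows"):
        emit(
            "window_stats.tsv",
            windows.windowed_pi(
                matrix, window=config.window, step=config.step, by_subpop=config.by_subpop
            ),
        )

    with stage("structure"):
        kin = relatedness.vanraden_kinship(matrix)
        emit("kinship.tsv", kin.to_frame().reset_index(names="sample_id"))
        grm = relatedness.standardized_grm(matrix)
        emit("grm.tsv", grm.to_frame().reset_index(names="sample_id"))
        pca_res = relatedness.pca(grm, k=config.n_evs)
        emit(
            "pca.tsv",
            pca_res.scores_frame(),
            meta={
                "eigenvalues": ",".join(f"{v:.6g}" for v in pca_res.eigenvalues),
                "variance_explained": ",".join(
                    f"{v:.6g}" for v in pca_res.variance_explained
                ),
            },
        )
        rogers = relatedness.rogers_distance(matrix)
        emit("rogers_distance.tsv", rogers.to_frame().reset_index(names="sample_id"))
        tree = relatedness.neighbor_joining(rogers)
        tree_path = out / "nj_tree.nwk"
        tree_path.write_text(tree.to_newick() + "\n")
        written.append(tree_path)

    with stage("differentiation"):
        per_snp = fst.wc_fst_per_snp(matrix)
        emit("fst_per_snp.tsv", per_snp)
        emit(
            "fst_pairwise.tsv",
            fst.pairwise_fst_matrix(matrix, n_perm=config.n_perm_fst, rng=config.seed),
        )
        emit(
            "amova.tsv",
            fst.amova(matrix, n_perm=config.n_perm_amova, rng=config.seed + 1).table,
        )

    with stage("ld"):
        pairs = ld.ld_scan(matrix, max_distance_bp=config.ld_max_distance_bp)
        emit("ld_pairs.tsv", pairs)
        fit = ld.fit_ld_decay(pairs, matrix.n_samples, threshold=config.ld_threshold)
        emit(
            "ld_fit.tsv",
            pd.DataFrame(
                [
                    {
                        "beta": fit.beta,
                        "n_samples": fit.n_samples,
                        "threshold": fit.threshold,
                        "decay_mb": fit.decay_mb,
                        "n_pairs": fit.n_pairs,
                    }
                ]
            ),
        )

    with stage("eigengwas"):
        scan = eigengwas.eigengwas_scan(matrix, pca_res)
        emit("eigengwas_scan.tsv", scan)
        diag = eigengwas.scan_diagnostics(pca_res, scan, grm)
        emit("eigengwas_diagnostics.tsv", diag, meta=dict(diag.attrs))
        threshold = config.cutoff
        if config.n_perm_threshold:
            threshold = max(
                threshold,
                eigengwas.permutation_threshold(
                    matrix,
                    pca_res,
                    ev=1,
                    n_perm=config.n_perm_threshold,
                    rng=config.seed + 2,
                ),
            )
        sig = eigengwas.select_significant(scan, minus_log10_cutoff=threshold)
        regions = eigengwas.merge_regions(sig, flank_bp=config.flank_bp, per_snp_fst=per_snp)
        emit(
            "selection_regions.tsv",
            regions,
            meta={
                "cutoff": threshold,
                "n_regions": len(regions),
                "n_unique_regions": eigengwas.count_unique_regions(regions),
            },
        )

    manifest = {
        "tool": "eigensel 0.1.0",
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "checksums": {p.name: _checksum(p) for p in written},
        "timings_s": timings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
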