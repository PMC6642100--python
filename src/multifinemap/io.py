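"""Reading and writing studies, posteriors and run manifests.

Genotypes travel as VCF (hard GT calls, one sample per individual) with a
tab-separated sample table (id, status, population, covariate columns), or
as a delimited dosage matrix (header row of SNP ids, one row per
individual).  Coordinates are 1-based inclusive throughout, matching the
convention of region names like ``10p-6030000-6220000``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .finemap import ModelPosterior, SNPModel
from .simulate import CaseControlStudy

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "write_study",
    "load_study",
    "write_dosage_matrix",
    "load_dosage_matrix",
    "write_posterior",
    "load_posterior",
    "write_manifest",
]


@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self}")

    def __str__(self) -> str:
        return f"{self.chrom}-{self.start}-{self.end}"


def write_study(study: CaseControlStudy, prefix: str | Path, chrom: str = "1") -> None:
    """Write a study as <prefix>.vcf plus <prefix>.samples.tsv."""
    prefix = Path(prefix)
    n = study.n_ind
    sample_ids = [f"ind{i + 1}" for i in range(n)]
    with open(prefix.with_suffix(".vcf"), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, snp in enumerate(study.snp_ids):
            calls = "\t".join(gt_strings[int(d)] for d in study.dosages[:, j])
            fh.write(
                f"{chrom}\t{study.positions[j]}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
            )
    tab = pd.DataFrame(
        {
            "id": sample_ids,
            "status": study.status,
            "population": study.population,
        }
    )
    for c in range(study.covariates.shape[1]):
        tab[f"cov{c + 1}"] = study.covariates[:, c]
    tab.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index=False)


def load_study(
    genotype_path: str | Path,
    sample_path: str | Path,
    region: Region | None = None,
    multiallelic: str = "skip",
) -> CaseControlStudy:
    """Load a study from VCF (or dosage matrix) plus a sample table.

    VCF GT calls are read as alternate-allele dosages; multi-allelic sites
    are skipped (with a logged count) or rejected per ``multiallelic``.
    ``region`` restricts SNPs, 1-based inclusive.
    """
    genotype_path = Path(genotype_path)
    samples = pd.read_csv(sample_path, sep="\t", dtype={"id": str})
    for col in ("id", "status"):
        if col not in samples.columns:
            raise ValueError(f"sample table {sample_path} lacks column {col!r}")
    if genotype_path.suffix == ".vcf" or genotype_path.name.endswith(".vcf.gz"):
        snp_ids, positions, dosages, vcf_samples = _read_vcf(
            genotype_path, region, multiallelic
        )
        if list(samples["id"]) != list(vcf_samples):
            raise ValueError(
                f"sample ids in {sample_path} do not match VCF sample columns "
                f"of {genotype_path}"
            )
    else:
        mat = load_dosage_matrix(genotype_path)
        snp_ids = list(mat.columns)
        positions = np.arange(1, len(snp_ids) + 1) * 1000
        dosages = mat.to_numpy(dtype=np.int8)
        if len(samples) != dosages.shape[0]:
            raise ValueError(
                f"{sample_path} lists {len(samples)} samples but "
                f"{genotype_path} has {dosages.shape[0]} rows"
            )
        if region is not None:
            raise ValueError("region filtering requires VCF input with positions")
    if len(snp_ids) == 0:
        raise ValueError(f"no SNPs remain in {genotype_path} for region {region}")
    cov_cols = [c for c in samples.columns if c.startswith("cov")]
    population = (
        samples["population"].to_numpy()
        if "population" in samples.columns
        else None
    )
    return CaseControlStudy(
        dosages=dosages,
        snp_ids=snp_ids,
        status=samples["status"].to_numpy(dtype=np.int32),
        covariates=samples[cov_cols].to_numpy(dtype=float)
        if cov_cols
        else None,
        population=population,
        positions=np.asarray(positions),
    )


def _read_vcf(path: Path, region: Region | None, multiallelic: str):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    snp_ids: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if region is not None:
            if var.CHROM != region.chrom or not (
                region.start <= var.POS <= region.end
            ):
                continue
        if len(var.ALT) != 1:
            n_multi += 1
            if multiallelic == "skip":
                continue
            raise ValueError(
                f"multi-allelic site {var.ID or var.POS} in {path} "
                "(multiallelic='error')"
            )
        gt = var.gt_types.copy()  # 0/1/2 alt dosage, 3 = missing under gts012
        if np.any(gt == 3):
            raise ValueError(f"missing genotypes at {var.ID or var.POS} in {path}")
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        rows.append(gt.astype(np.int8))
    if n_multi:
        logger.warning("%s: skipped %d multi-allelic sites", path, n_multi)
    dosages = (
        np.stack(rows, axis=1) if rows else np.empty((len(vcf_samples), 0), np.int8)
    )
    return snp_ids, np.array(positions), dosages, vcf_samples


def write_dosage_matrix(study: CaseControlStudy, path: str | Path) -> None:
    """Delimited dosage dialect: header of SNP ids, one row per individual."""
    pd.DataFrame(study.dosages, columns=study.snp_ids).to_csv(
        path, sep="\t", index=False
    )


def load_dosage_matrix(path: str | Path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t")
    bad = ~mat.isin([0, 1, 2]).all(axis=0)
    if bad.any():
        raise ValueError(
            f"{path}: non-dosage values in columns {list(mat.columns[bad])}"
        )
    return mat


def write_posterior(posterior: ModelPosterior, path: str | Path) -> None:
    """Posterior table as TSV: model (comma-joined ids), size, logBF, logprior, pp."""
    rows = [
        {
            "model": ",".join(m.snps) if m.snps else "",
            "size": m.size,
            "logBF": lbf,
            "logprior": lpr,
            "pp": pp,
        }
        for m, (lbf, lpr, pp) in sorted(
            posterior.entries.items(), key=lambda kv: -kv[1][2]
        )
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_posterior(
    path: str | Path, disease: int, n_snps_region: int
) -> ModelPosterior:
    tab = pd.read_csv(path, sep="\t", keep_default_na=False)
    entries = {}
    for _, row in tab.iterrows():
        model = SNPModel(
            tuple(str(row["model"]).split(",")) if row["model"] else ()
        )
        entries[model] = (
            float(row["logBF"]),
            float(row["logprior"]),
            float(row["pp"]),
        )
    return ModelPosterior(
        disease=disease, entries=entries, n_snps_region=n_snps_region
    )


def write_manifest(path: str | Path, config: dict, seed: int) -> dict:
    """Run manifest: canonical config hash, seed and library versions."""
    import scipy

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "multifinemap": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
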