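"""SNP quality-control filters for case/control studies.

Filters are applied in a fixed order; each excluded SNP is reported with the
first rule it triggered.  Imputation-quality rules (info score, certainty)
apply only when imputation metadata is supplied — hard-called genotypes
carry none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CaseControlStudy

__all__ = ["QCThresholds", "hwe_z", "qc_filter"]


@dataclass(frozen=True)
class QCThresholds:
    info_min: float = 0.3
    certainty_min: float = 0.98
    hwe_z_max: float = 4.0
    maf_min: float = 0.005
    call_rate_min: float = 0.99
    call_rate_diff_max: float = 0.05


def hwe_z(genotypes: np.ndarray) -> float:
    """Hardy-Weinberg Z statistic from the inbreeding coefficient.

    F = 1 - observed_het / expected_het with expected_het = 2 p (1-p) n;
    Z = sqrt(n) F, so an excess or deficit of heterozygotes of one full
    unit of F at n individuals gives |Z| = sqrt(n).
    """
    g = np.asarray(genotypes, dtype=float)
    g = g[~np.isnan(g)]
    n = len(g)
    if n == 0:
        return 0.0
    p = g.mean() / 2
    if p in (0.0, 1.0):
        return 0.0
    het = np.mean(g == 1)
    f = 1 - het / (2 * p * (1 - p))
    return float(np.sqrt(n) * f)


@dataclass
class ExclusionReport:
    """Per-SNP exclusion record: SNP id and the rule that triggered."""

    excluded: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": list(self.excluded), "rule": list(self.excluded.values())}
        )

    def __len__(self) -> int:
        return len(self.excluded)


def qc_filter(
    study: CaseControlStudy,
    thresholds: QCThresholds = QCThresholds(),
    info: dict[str, float] | None = None,
    certainty: dict[str, float] | None = None,
    missing: np.ndarray | None = None,
) -> tuple[CaseControlStudy, ExclusionReport]:
    """Apply the SNP exclusion rules; returns the filtered study and report.

    Rules in order: info score < 0.3 and certainty < 0.98 (only with
    imputation metadata); |Z| for HWE > 4 in controls; MAF < 0.5% in
    controls; call rate < 99% in any case or control group; absolute
    call-rate difference between controls and any case group > 5%.
    ``missing`` is an optional boolean mask (individuals x SNPs) of missing
    calls; the simulator's complete data make the call-rate rules no-ops.
    """
    controls = study.status == 0
    if not controls.any():
        raise ValueError("QC needs a control class for HWE/MAF checks")
    report = ExclusionReport()
    t = thresholds
    n_dis = study.n_diseases
    for j, snp in enumerate(study.snp_ids):
        if info is not None and snp in info and info[snp] < t.info_min:
            report.excluded[snp] = f"info<{t.info_min}"
            continue
        if certainty is not None and snp in certainty and certainty[snp] < t.certainty_min:
            report.excluded[snp] = f"certainty<{t.certainty_min}"
            continue
        g_ctrl = study.dosages[controls, j].astype(float)
        if missing is not None:
            g_ctrl = g_ctrl[~missing[controls, j]]
        z = hwe_z(g_ctrl)
        if abs(z) > t.hwe_z_max:
            report.excluded[snp] = f"|Z_HWE|>{t.hwe_z_max}"
            continue
        maf = g_ctrl.mean() / 2 if len(g_ctrl) else 0.0
        maf = min(maf, 1 - maf)
        if maf < t.maf_min:
            report.excluded[snp] = f"MAF<{t.maf_min}"
            continue
        if missing is not None:
            rates = {}
            for k in range(n_dis + 1):
                grp = study.status == k
                if grp.any():
                    rates[k] = 1 - missing[grp, j].mean()
            if any(r < t.call_rate_min for r in rates.values()):
                report.excluded[snp] = f"call rate<{t.call_rate_min}"
                continue
            if any(
                abs(rates[0] - rates[k]) > t.call_rate_diff_max
                for k in rates
                if k != 0
            ):
                report.excluded[snp] = f"call rate diff>{t.call_rate_diff_max}"
                continue
    if not report.excluded:
        return study, report
    keep = [j for j, s in enumerate(study.snp_ids) if s not in report.excluded]
    filtered = CaseControlStudy(
        dosages=study.dosages[:, keep],
        snp_ids=[study.snp_ids[j] for j in keep],
        status=study.status,
        covariates=study.covariates,
        population=study.population,
        shared_controls=study.shared_controls,
        positions=study.positions[keep],
    )
    return filtered, report
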