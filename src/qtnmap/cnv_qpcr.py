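"""Relative copy-number quantification from qPCR and association regression.

Quantification follows the efficiency-corrected relative quantity model:
with amplification efficiency E (E = 2 means perfect doubling per cycle),
the initial template amount behind a threshold cycle Ct is proportional to
E^-Ct.  Normalizing a target probe against a non-CNV reference probe in the
same sample cancels DNA input:

    RQ_s = E_t^(-mean Ct_t,s) / E_r^(-mean Ct_r,s)

and the normalized relative quantities (NRQ) are rescaled so the largest
sample takes a chosen value (default 2, i.e. two copies per diploid
genome for the top sample).  Replicate spread propagates to an NRQ standard
error by the first-order delta method.

Probe quality control uses the standard-curve slope of Ct against log10
template quantity — efficiency% = 100 * (10^(-1/slope) - 1) — and the
LOD-to-NTC Ct gap, which bounds the nonspecific amplification fraction by
2^-delta_Ct under perfect doubling.

Association is plain OLS of sire breeding values on copy number and/or
marker genotype dosage (0/1/2), singly or jointly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .core import BreedingValueTable
from .errors import DomainError, SingularityError, ValidationError


@dataclass
class QpcrPanel:
    """Replicate Ct values per sample and probe, with probe metadata.

    ``probe_roles`` maps each probe to ``target`` or ``reference``;
    ``efficiencies`` default to 2.0 (100%) unless standard curves supplied
    better estimates.
    """

    ct: dict[tuple[str, str], tuple[float, ...]]
    probe_roles: dict[str, str]
    efficiencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(r == "reference" for r in self.probe_roles.values()):
            raise ValidationError("panel needs at least one reference probe")
        for (s, p), reps in self.ct.items():
            if p not in self.probe_roles:
                raise ValidationError(f"Ct entry for unknown probe {p!r}")
            if len(reps) < 1:
                raise ValidationError(f"{s}/{p}: at least one replicate required")
            if any(not np.isfinite(c) or c <= 0 for c in reps):
                raise ValidationError(f"{s}/{p}: Ct values must be finite and positive")
        for p, e in self.efficiencies.items():
            if not (1.0 < e <= 2.2):
                raise DomainError(f"probe {p}: efficiency {e} outside (1, 2.2]")

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for s, _ in self.ct:
            if s not in seen:
                seen.append(s)
        return seen

    @property
    def probes(self) -> list[str]:
        return list(self.probe_roles)

    def efficiency(self, probe: str) -> float:
        return self.efficiencies.get(probe, 2.0)


@dataclass
class StandardCurve:
    """OLS fit of mean Ct against log10 template quantity for one probe."""

    log10_quantity: list[float]
    mean_ct: list[float]
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * (10.0 ** (-1.0 / self.slope) - 1.0)

    @property
    def efficiency(self) -> float:
        """Fold amplification per cycle (2.0 = perfect doubling)."""
        return 1.0 + self.efficiency_percent / 100.0

    @property
    def valid(self) -> bool:
        return self.slope < 0


@dataclass
class CopyNumberEstimate:
    sample: str
    probe: str
    nrq: float
    se: float


def normalized_relative_quantity(panel: QpcrPanel, target_probe: str,
                                 reference_probe: str, scale_max: float = 2.0,
                                 *, replicate_summary: str = "mean"
                                 ) -> list[CopyNumberEstimate]:
    """Efficiency-corrected NRQ per sample, rescaled so max = ``scale_max``.

    ``replicate_summary`` is ``mean`` (arithmetic mean Ct, the default) or
    ``geometric`` (geometric mean of per-replicate RQs; for paired
    replicates this equals the mean-Ct route and differs only with ragged
    replicates).  Samples missing either probe are excluded with a warning.
    """
    for p in (target_probe, reference_probe):
        if p not in panel.probe_roles:
            raise ValidationError(f"probe {p!r} not in panel")
    e_t, e_r = panel.efficiency(target_probe), panel.efficiency(reference_probe)
    if e_t <= 1.0 or e_r <= 1.0:
        raise DomainError("efficiencies must exceed 1.0")

    log_rq: dict[str, float] = {}     # log RQ, numerically safer than E^-Ct
    log_var: dict[str, float] = {}
    for s in panel.samples:
        ct_t = panel.ct.get((s, target_probe))
        ct_r = panel.ct.get((s, reference_probe))
        if ct_t is None or ct_r is None:
            warnings.warn(f"sample {s}: missing {'target' if ct_t is None else 'reference'} "
                          "probe, excluded", stacklevel=2)
            continue
        if replicate_summary == "geometric":
            per_rep = [-math.log(e_t) * c for c in ct_t]
            mt, vt = float(np.mean(per_rep)), _mean_var(per_rep)
            per_rep_r = [-math.log(e_r) * c for c in ct_r]
            mr, vr = float(np.mean(per_rep_r)), _mean_var(per_rep_r)
            log_rq[s] = mt - mr
            log_var[s] = vt + vr
        elif replicate_summary == "mean":
            mt, mr = float(np.mean(ct_t)), float(np.mean(ct_r))
            log_rq[s] = -math.log(e_t) * mt + math.log(e_r) * mr
            log_var[s] = (math.log(e_t) ** 2 * _mean_var(ct_t)
                          + math.log(e_r) ** 2 * _mean_var(ct_r))
        else:
            raise ValidationError(f"unknown replicate_summary {replicate_summary!r}")

    if not log_rq:
        return []
    top = max(log_rq.values())
    out = []
    for s, lr in log_rq.items():
        nrq = scale_max * math.exp(lr - top)
        # first-order delta method: se(NRQ) = NRQ * sd(log RQ)
        out.append(CopyNumberEstimate(s, target_probe, nrq,
                                      nrq * math.sqrt(log_var[s])))
    return out


def _mean_var(values: Sequence[float]) -> float:
    """Variance of the replicate mean (sample variance / r); 0 for r = 1."""
    if len(values) < 2:
        return 0.0
    return float(np.var(values, ddof=1)) / len(values)


def fit_standard_curve(log10_quantity: Sequence[float],
                       mean_ct: Sequence[float]) -> StandardCurve:
    """Least-squares standard curve; slope -3.32 corresponds to 100% efficiency."""
    if len(log10_quantity) != len(mean_ct):
        raise ValidationError("quantity and Ct vectors must match in length")
    if len(log10_quantity) < 3:
        raise ValidationError("standard curve needs at least 3 dilution points")
    fit = scipy.stats.linregress(log10_quantity, mean_ct)
    curve = StandardCurve(list(map(float, log10_quantity)),
                          list(map(float, mean_ct)),
                          float(fit.slope), float(fit.intercept),
                          float(fit.rvalue) ** 2)
    if not curve.valid:
        warnings.warn(f"standard curve slope {curve.slope:.3f} is non-negative; "
                      "curve flagged invalid", stacklevel=2)
    return curve


def ntc_specificity_bound(delta_ct: float) -> float:
    """Percent bound on nonspecific product from the LOD-to-NTC Ct gap.

    Assuming perfect doubling, a no-template control crossing threshold
    ``delta_ct`` cycles after the lowest standard implies its product pool
    is at most 100 * 2^-delta_ct percent of a true signal.
    """
    if delta_ct < 0:
        raise DomainError("delta Ct must be >= 0")
    return 100.0 * 2.0 ** (-delta_ct)


@dataclass
class RegressionResult:
    """Per-predictor OLS estimates for a breeding-value association model."""

    predictors: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    intercept: float
    r_squared: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predictor": self.predictors,
            "coef": [self.coef[k] for k in self.predictors],
            "se": [self.se[k] for k in self.predictors],
            "t": [self.t[k] for k in self.predictors],
            "p": [self.p[k] for k in self.predictors],
        })


def regress_breeding_values(bv: BreedingValueTable,
                            predictors: Mapping[str, Mapping[str, float]]
                            ) -> RegressionResult:
    """OLS of breeding values on one or two predictors (complete cases).

    ``predictors`` maps predictor name -> {sire -> value}; typical choices
    are a copy-number vector (NRQ) and a marker genotype dosage (0/1/2).
    """
    if not 1 <= len(predictors) <= 2:
        raise ValidationError("provide one or two predictors")
    names = list(predictors)
    sires = [s for s in bv
             if all(s in predictors[n] for n in names)]
    if len(sires) < 3:
        raise ValidationError(f"need >= 3 complete cases, have {len(sires)}")
    y = np.array([bv[s] for s in sires], dtype=float)
    X = np.column_stack([[predictors[n][s] for s in sires] for n in names])
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularityError(
            f"predictors {names} are perfectly collinear (or constant)")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        predictors=names,
        coef={n: float(fit.params[i + 1]) for i, n in enumerate(names)},
        se={n: float(fit.bse[i + 1]) for i, n in enumerate(names)},
        t={n: float(fit.tvalues[i + 1]) for i, n in enumerate(names)},
        p={n: float(fit.pvalues[i + 1]) for i, n in enumerate(names)},
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n=len(sires),
    )


# ---------------------------------------------------------------------------
# I/O: Ct table (sample, probe, replicate, ct) and standard-curve table
# (probe, log10_qty, ct); duplicated rows aggregate idempotently.
# ---------------------------------------------------------------------------


def read_qpcr_table(path, probe_roles: Mapping[str, str],
                    efficiencies: Mapping[str, float] | None = None) -> QpcrPanel:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "probe": str})
    for col in ("sample", "probe", "replicate", "ct"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    df = df.drop_duplicates(subset=["sample", "probe", "replicate"])
    ct: dict[tuple[str, str], tuple[float, ...]] = {}
    for (s, p), grp in df.groupby(["sample", "probe"], sort=False):
        grp = grp.sort_values("replicate")
        ct[(s, p)] = tuple(float(c) for c in grp["ct"])
    return QpcrPanel(ct, dict(probe_roles), dict(efficiencies or {}))


def write_qpcr_table(panel: QpcrPanel, path) -> None:
    rows = []
    for (s, p), reps in panel.ct.items():
        for r, c in enumerate(reps, start=1):
            rows.append({"sample": s, "probe": p, "replicate": r, "ct": c})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def estimates_to_frame(estimates: Sequence[CopyNumberEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{"sample": e.sample, "probe": e.probe,
                          "nrq": e.nrq, "se": e.se} for e in estimates])
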