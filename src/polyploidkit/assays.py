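"""ORAC antioxidant quantification and relative metabolite content.

The oxygen radical absorbance capacity (ORAC) assay tracks the decay of a
fluorescent probe under peroxyl-radical attack; antioxidants delay the
decay, so the area under the fluorescence decay curve (AUC) grows with
antioxidant capacity. Per well the AUC is the trapezoidal integral of
relative fluorescence f_i / f_0 over cycle index; the blank AUC is
subtracted to give the net AUC, which is calibrated against a Trolox
standard curve (ordinary least squares of net AUC on concentration, 12.5 to
100 uM) and reported as Trolox equivalents. Technical replicates must agree
to a coefficient of variation below 0.20.

Relative metabolite content from LC-MS peak areas is
peak_area / internal_standard_area / extracted_mass (peak area/IS/gdw).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "Well",
    "PlateRun",
    "StandardCurve",
    "OracResult",
    "auc_curve",
    "net_auc",
    "fit_standard_curve",
    "te_value",
    "cv_gate",
    "quantify_plate",
    "relative_content",
]

CYCLES = 70
CYCLE_SECONDS = 90.0
CV_LIMIT = 0.20
STANDARD_RANGE_UM = (12.5, 100.0)
DEFAULT_SAMPLE_VOLUME_UL = 25.0  # sample aliquot per reaction well


@dataclass
class Well:
    well_id: str
    role: str  # blank | standard | sample
    fluorescence: np.ndarray  # one reading per cycle
    concentration_uM: float | None = None  # standards only
    dilution: float = 1.0  # samples only
    mass_mg: float | None = None  # samples only
    sample_id: str | None = None  # groups technical replicates

    def __post_init__(self):
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.role not in ("blank", "standard", "sample"):
            raise ValidationError(f"well {self.well_id!r}: unknown role {self.role!r}")
        if (self.fluorescence < 0).any():
            raise ValidationError(f"well {self.well_id!r}: negative fluorescence")
        if self.role == "standard" and self.concentration_uM is None:
            raise ValidationError(f"well {self.well_id!r}: standard without concentration")


@dataclass
class PlateRun:
    wells: list[Well]
    cycle_seconds: float = CYCLE_SECONDS

    def __post_init__(self):
        concs = {w.concentration_uM for w in self.wells if w.role == "standard"}
        if self.wells and len(concs) < 2 and any(w.role == "standard" for w in self.wells):
            raise ValidationError("standards must span at least 2 distinct concentrations")

    def by_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.role == role]


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # net AUC per uM
    intercept: float
    r_squared: float


@dataclass
class OracResult:
    sample_id: str
    net_auc: list[float]
    te_uM: list[float]  # per technical replicate
    value_nmol_te_per_mg: float  # mean over passing replicates
    cv: float
    passed: bool
    flags: list[str] = field(default_factory=list)


def auc_curve(series) -> float:
    """Trapezoidal AUC of relative fluorescence f_i/f_0 over cycle index.

    Dimensionless (cycles); invariant to uniform gain because of the f_0
    normalisation. A flat series of n cycles gives n-1.
    """
    f = np.asarray(series, dtype=float)
    if f.size < 2:
        raise ValidationError("need at least 2 cycles for an AUC")
    if f[0] == 0:
        raise ValidationError("undefined decay curve: first-cycle fluorescence is 0")
    return float(np.trapezoid(f / f[0]))


def net_auc(sample_auc: float, blank_auc: float) -> float:
    """Blank-corrected AUC; negative values are allowed (flagged upstream)."""
    return sample_auc - blank_auc


def fit_standard_curve(concentrations, net_aucs) -> StandardCurve:
    """Ordinary least squares of net AUC on Trolox concentration (uM)."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(net_aucs, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValidationError("standard curve needs >= 2 distinct concentrations")
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def te_value(net: float, curve: StandardCurve, dilution: float = 1.0,
             mass_mg: float | None = None,
             sample_volume_uL: float = DEFAULT_SAMPLE_VOLUME_UL) -> tuple[float, float | None]:
    """Trolox equivalents from a net AUC.

    Returns (TE concentration in uM, final value in nmol TE / mg FW or None
    without a tissue mass). The final value multiplies the well TE
    concentration by the sample aliquot volume (uM * uL * 1e-3 = nmol in
    the well) and the extract dilution factor, then divides by tissue mass.
    """
    if curve.slope == 0:
        raise ValidationError("degenerate standard curve: zero slope")
    te_uM = (net - curve.intercept) / curve.slope
    if mass_mg is None:
        return te_uM, None
    if mass_mg <= 0:
        raise ValidationError("tissue mass must be positive")
    nmol = te_uM * sample_volume_uL * 1e-3 * dilution
    return te_uM, nmol / mass_mg


def cv_gate(replicate_values) -> tuple[float, bool]:
    """Coefficient of variation (sample SD / mean) across technical
    replicates; passes iff CV < 0.20."""
    v = np.asarray(replicate_values, dtype=float)
    if v.size < 2:
        raise ValidationError("CV needs >= 2 technical replicates")
    mean = v.mean()
    if mean == 0:
        raise ValidationError("CV undefined: replicate mean is 0")
    cv = float(v.std(ddof=1) / mean)
    return cv, cv < CV_LIMIT


def quantify_plate(run: PlateRun,
                   sample_volume_uL: float = DEFAULT_SAMPLE_VOLUME_UL) -> tuple[StandardCurve, list[OracResult]]:
    """Full ORAC quantification of one plate.

    Blank AUC is the mean over blank wells; the standard curve is fit on
    blank-corrected standard AUCs; samples are grouped by sample_id into
    technical replicates and gated on CV < 0.20.
    """
    blanks = run.by_role("blank")
    if not blanks:
        raise ValidationError("plate has no blank wells")
    blank_auc = float(np.mean([auc_curve(w.fluorescence) for w in blanks]))

    standards = run.by_role("standard")
    if not standards:
        raise ValidationError("plate has no standard wells")
    curve = fit_standard_curve(
        [w.concentration_uM for w in standards],
        [net_auc(auc_curve(w.fluorescence), blank_auc) for w in standards])

    groups: dict[str, list[Well]] = {}
    for w in run.by_role("sample"):
        groups.setdefault(w.sample_id or w.well_id, []).append(w)

    results = []
    for sample_id, wells in sorted(groups.items()):
        nets, tes, finals, flags = [], [], [], []
        for w in wells:
            net = net_auc(auc_curve(w.fluorescence), blank_auc)
            if net < 0:
                flags.append(f"{w.well_id}: negative net AUC")
            te_uM, final = te_value(net, curve, dilution=w.dilution,
                                    mass_mg=w.mass_mg,
                                    sample_volume_uL=sample_volume_uL)
            nets.append(net)
            tes.append(te_uM)
            finals.append(final)
        if len(wells) >= 2:
            cv, passed = cv_gate(tes)
        else:
            cv, passed = float("nan"), False
            flags.append("single technical replicate: CV gate not evaluable")
        value = float(np.mean([f for f in finals if f is not None])) \
            if any(f is not None for f in finals) else float("nan")
        results.append(OracResult(sample_id=sample_id, net_auc=nets, te_uM=tes,
                                  value_nmol_te_per_mg=value, cv=cv,
                                  passed=passed, flags=flags))
    return curve, results


def relative_content(peak_area: float, is_area: float,
                     extracted_mass_g: float) -> float:
    """Relative metabolite content: peak area / internal standard area /
    extracted tissue mass (peak area/IS/gdw)."""
    if is_area <= 0:
        raise ValidationError("internal standard area must be positive")
    if extracted_mass_g <= 0:
        raise ValidationError("extracted mass must be positive")
    return peak_area / is_area / extracted_mass_g


def results_table(results: list[OracResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id,
        "n_replicates": len(r.te_uM),
        "mean_te_uM": float(np.mean(r.te_uM)),
        "value_nmol_te_per_mg": r.value_nmol_te_per_mg,
        "cv": r.cv,
        "passed": r.passed,
        "flags": "; ".join(r.flags),
    } for r in results])
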