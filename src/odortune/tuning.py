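"""Receptor tuning breadth, tuning curves, and mutant-vs-wild-type tests.

Lifetime sparseness quantifies how narrowly a receptor is tuned across a
ligand panel of size n::

    S = (1 / (1 - 1/n)) * (1 - (sum(res_i)/n)**2 / (sum(res_i**2)/n))

computed after setting inhibitory (negative) responses to zero. S = 0 for
perfectly flat tuning, S = 1 when exactly one ligand elicits a response.

Group comparisons of per-replicate log EC50s between mutants and the
wild-type control follow the assay's decision rule: one-way ANOVA with
Dunnett-adjusted pairwise comparisons against the control, except that a
mutant whose EC50s were incalculably high (censored) is compared with the
robust Brown-Forsythe procedure when Bartlett's test shows the groups'
variances are not homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    ComparisonError,
    InvalidParameterError,
    UndefinedSparsenessError,
)
from .doseresponse import CENSOR_LOG_EC50

__all__ = [
    "TuningProfile",
    "ComparisonResult",
    "lifetime_sparseness",
    "build_tuning_curve",
    "count_active",
    "compare_to_wildtype",
    "DEFAULT_LABEL_MAP",
]

#: p-value thresholds -> significance labels (most stringent first).
DEFAULT_LABEL_MAP = ((1e-4, "****"), (1e-3, "***"), (1e-2, "*"))


def lifetime_sparseness(responses, zero_negative: bool = True) -> float:
    """Tuning-breadth statistic in [0, 1] over a panel of responses.

    Inhibitory responses (values below 0) are set to 0 before the
    calculation. Raises :class:`UndefinedSparsenessError` when every
    zeroed response is zero (the statistic is 0/0 there).
    """
    res = np.asarray(responses, dtype=float)
    if res.ndim != 1 or res.size < 2:
        raise InvalidParameterError("sparseness needs a 1-D panel of >= 2 responses")
    if zero_negative:
        res = np.where(res < 0, 0.0, res)
    n = res.size
    sum_sq = float(np.sum(res**2))
    if sum_sq == 0.0:
        raise UndefinedSparsenessError(
            "all responses are zero after inhibitory zeroing; sparseness undefined"
        )
    mean_sq = float(np.sum(res) / n) ** 2
    return float((1.0 / (1.0 - 1.0 / n)) * (1.0 - mean_sq / (sum_sq / n)))


@dataclass
class TuningProfile:
    """One receptor's responses (activity indices by default) over a panel."""

    receptor_id: str
    panel: list[str]
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if len(self.panel) != self.responses.size:
            raise AlignmentError(
                f"{self.receptor_id}: panel has {len(self.panel)} ligands but "
                f"{self.responses.size} responses"
            )

    @property
    def n(self) -> int:
        return len(self.panel)

    @property
    def sparseness(self) -> float:
        return lifetime_sparseness(self.responses)

    @classmethod
    def from_fits(
        cls, fits: pd.DataFrame, receptor_id: str, metric: str = "activity_index"
    ) -> "TuningProfile":
        sub = fits[fits["receptor_id"] == receptor_id].sort_values("ligand_id")
        return cls(receptor_id, sub["ligand_id"].tolist(), sub[metric].to_numpy())


def build_tuning_curve(
    profiles: list[TuningProfile], reference_receptor: str
) -> pd.DataFrame:
    """Panel ordered by descending response in the reference receptor.

    All profiles must share the same ligand panel; mutant response vectors
    are re-ordered identically so they overlay the wild-type curve. Ties
    in the reference responses break by ligand name ascending.
    """
    by_id = {p.receptor_id: p for p in profiles}
    if reference_receptor not in by_id:
        raise AlignmentError(f"reference receptor {reference_receptor!r} not supplied")
    ref = by_id[reference_receptor]
    ref_set = set(ref.panel)
    for p in profiles:
        if set(p.panel) != ref_set:
            diff = sorted(set(p.panel) ^ ref_set)
            raise AlignmentError(
                f"panel mismatch between {p.receptor_id} and {reference_receptor}: {diff}"
            )
    order = sorted(
        range(ref.n), key=lambda i: (-ref.responses[i], ref.panel[i])
    )
    ligands = [ref.panel[i] for i in order]
    out = pd.DataFrame({"ligand_id": ligands})
    for p in profiles:
        lookup = dict(zip(p.panel, p.responses))
        out[p.receptor_id] = [lookup[l] for l in ligands]
    return out


@dataclass(frozen=True)
class ActivityCriterion:
    """Predicate deciding whether a dose-response record counts as an agonist."""

    require_uncensored: bool = True
    min_activity_index: float = 0.0

    def describe(self) -> str:
        parts = []
        if self.require_uncensored:
            parts.append("non-censored fit")
        parts.append(f"activity_index > {self.min_activity_index:g}")
        return " AND ".join(parts)

    def __call__(self, row) -> bool:
        if self.require_uncensored and bool(row["censored"]):
            return False
        return float(row["activity_index"]) > self.min_activity_index


def count_active(
    fits: pd.DataFrame, criterion: ActivityCriterion | None = None
) -> dict:
    """Fraction of the panel that are agonists under an explicit criterion.

    Returns a record with the fraction, counts, and the criterion echoed
    so downstream tables are self-describing.
    """
    criterion = criterion or ActivityCriterion()
    n = len(fits)
    hits = int(sum(bool(criterion(row)) for _, row in fits.iterrows())) if n else 0
    return {
        "n_panel": n,
        "n_active": hits,
        "fraction_active": hits / n if n else float("nan"),
        "criterion": criterion.describe(),
    }


@dataclass
class ComparisonResult:
    mutant_id: str
    control_id: str
    test_used: str               # "anova_dunnett" | "brown_forsythe"
    p_value: float
    significance_label: str
    anova_p: float = float("nan")
    bartlett_p: float = float("nan")
    n_mutant: int = 0
    n_control: int = 0
    notes: str = ""
    extras: dict = field(default_factory=dict)


def _label(p: float, label_map) -> str:
    for threshold, label in sorted(label_map, key=lambda t: t[0]):
        if p < threshold:
            return label
    return "NS"


def compare_to_wildtype(
    groups: dict[str, np.ndarray],
    control_id: str,
    *,
    alpha_bartlett: float = 0.05,
    censor_value: float = CENSOR_LOG_EC50,
    censored_flags: dict[str, np.ndarray] | None = None,
    label_map=DEFAULT_LABEL_MAP,
) -> list[ComparisonResult]:
    """Compare each mutant's log EC50 replicates against the control.

    Decision logic per mutant: if its group (or the control) contains
    censored values — taken from ``censored_flags`` when given, otherwise
    inferred as equality with ``censor_value`` — AND Bartlett's test
    across all groups rejects variance homogeneity at ``alpha_bartlett``,
    the mutant is tested against the control with the Brown-Forsythe
    procedure (median-centred robust test). Otherwise its p-value is the
    Dunnett-adjusted comparison from the one-way ANOVA family.
    """
    if control_id not in groups:
        raise ComparisonError(f"control group {control_id!r} missing")
    mutants = [g for g in groups if g != control_id]
    if not mutants:
        raise ComparisonError("need at least one mutant group besides the control")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ComparisonError(f"group {name!r} has fewer than 2 replicates")

    def has_censored(name: str) -> bool:
        if censored_flags is not None and name in censored_flags:
            return bool(np.any(censored_flags[name]))
        return bool(np.any(arrays[name] == censor_value))

    all_groups = [arrays[control_id]] + [arrays[m] for m in mutants]
    # Bartlett degenerates when a group has zero variance (a fully censored
    # mutant pinned at the placeholder); treat that as rejection, which is
    # the conservative reading of "non-homogeneous variance".
    zero_var = any(np.var(g) == 0 for g in all_groups)
    if zero_var:
        bartlett_p = 0.0
    else:
        bartlett_p = float(stats.bartlett(*all_groups).pvalue)
    anova_p = float(stats.f_oneway(*all_groups).pvalue)

    dunnett_p = None
    plain = [m for m in mutants if not (has_censored(m) and bartlett_p < alpha_bartlett)]
    if plain:
        res = stats.dunnett(
            *[arrays[m] for m in plain], control=arrays[control_id]
        )
        dunnett_p = dict(zip(plain, np.atleast_1d(res.pvalue).astype(float)))

    out = []
    for mutant in mutants:
        if mutant in (dunnett_p or {}):
            p = dunnett_p[mutant]
            test = "anova_dunnett"
            notes = ""
        else:
            bf = stats.levene(arrays[control_id], arrays[mutant], center="median")
            p = float(bf.pvalue)
            test = "brown_forsythe"
            notes = "censored EC50s with non-homogeneous variance (Bartlett)"
        out.append(
            ComparisonResult(
                mutant_id=mutant,
                control_id=control_id,
                test_used=test,
                p_value=float(p),
                significance_label=_label(float(p), label_map),
                anova_p=anova_p,
                bartlett_p=bartlett_p,
                n_mutant=int(arrays[mutant].size),
                n_control=int(arrays[control_id].size),
                notes=notes,
            )
        )
    return out
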