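"""Feature panel: the dynamic clinical variables the pipeline models.

The default panel holds the 28 dynamic indicators retained after
missingness filtering in the source cohorts (vital signs, blood gas and
chemistry values, hematology, coagulation, and bedside scores), each with
its unit, a *plausible* physiologic range (out-of-range values are only
warned about) and a *hard* physical range (out-of-range values are
rejected at load time).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class VariableSpec:
    """One dynamic clinical variable.

    ``plausible_low/high`` bound what a clinician would accept without
    a second look; ``hard_low/high`` bound what is physically possible
    for the assay (loading rejects values outside the hard range only).
    """

    code: str
    unit: str
    plausible_low: float
    plausible_high: float
    hard_low: float
    hard_high: float
    dynamic: bool = True

    def __post_init__(self) -> None:
        if not self.plausible_low < self.plausible_high:
            raise ValueError(f"{self.code}: plausible_low must be < plausible_high")
        if not self.hard_low <= self.plausible_low:
            raise ValueError(f"{self.code}: hard_low must be <= plausible_low")
        if not self.hard_high >= self.plausible_high:
            raise ValueError(f"{self.code}: hard_high must be >= plausible_high")


@dataclass
class FeaturePanel:
    """Set of variables under analysis plus the missingness exclusion rule.

    ``missingness_threshold`` is the episode-level fraction of patients
    with *no* measurement of a variable above which the variable is
    excluded from modeling (strictly greater than; exactly at the
    threshold is retained).
    """

    variables: list[VariableSpec] = field(default_factory=list)
    missingness_threshold: float = 0.20

    def __post_init__(self) -> None:
        codes = [v.code for v in self.variables]
        if len(codes) != len(set(codes)):
            raise ValueError("variable codes must be unique")

    @property
    def codes(self) -> list[str]:
        return [v.code for v in self.variables]

    @property
    def dynamic_codes(self) -> list[str]:
        return [v.code for v in self.variables if v.dynamic]

    def __contains__(self, code: str) -> bool:
        return any(v.code == code for v in self.variables)

    def __getitem__(self, code: str) -> VariableSpec:
        for v in self.variables:
            if v.code == code:
                return v
        raise KeyError(code)


@dataclass
class CtwhConfig:
    """Parameters of the continuous time-window histogram stage.

    quantile_q
        Quantile of the pooled inter-measurement interval distribution
        used as the per-variable window size (the "P1" 70% quantile).
    r_threshold
        Pearson correlation above which a successive window is judged
        temporally continuous enough to reference.
    max_windows
        Cap on the number of referenced windows.
    grid_step_h
        Step of the regular imputation lattice, in hours.
    min_pairs
        Minimum complete window pairs needed before a lag correlation
        is trusted; below this the count falls back to 1.
    """

    quantile_q: float = 0.70
    r_threshold: float = 0.6
    max_windows: int = 4
    grid_step_h: float = 1.0
    min_pairs: int = 10
    per_patient_quantile: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile_q < 1.0:
            raise ValueError("quantile_q must lie in (0, 1)")
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.max_windows < 1:
            raise ValueError("max_windows must be >= 1")


# (code, unit, plausible_low, plausible_high, hard_low, hard_high)
# Plausible ranges follow pediatric reference intervals; pH, creatinine
# and Glasgow Coma Scale use the observed ranges reported for the source
# cohort (pH 7.10-7.55, Cr 8.84-309.4 umol/L, GCS 3-15).
_DEFAULT_VARIABLES: list[tuple[str, str, float, float, float, float]] = [
    ("T",    "degC",     35.0, 41.0,  25.0, 45.0),
    ("R",    "breaths/min", 10.0, 80.0, 0.0, 180.0),
    ("HR",   "beats/min",   50.0, 220.0, 0.0, 350.0),
    ("MAP",  "mmHg",     30.0, 120.0, 0.0, 250.0),
    ("DBP",  "mmHg",     20.0, 100.0, 0.0, 250.0),
    ("SBP",  "mmHg",     50.0, 160.0, 0.0, 300.0),
    ("INR",  "ratio",    0.8,  4.0,   0.1, 20.0),
    ("WBC",  "1e9/L",    1.0,  40.0,  0.0, 200.0),
    ("TB",   "umol/L",   2.0,  200.0, 0.0, 1000.0),
    ("Cr",   "umol/L",   8.84, 309.4, 0.0, 2000.0),
    ("LAC",  "mmol/L",   0.3,  15.0,  0.0, 40.0),
    ("PLT",  "1e9/L",    20.0, 800.0, 0.0, 3000.0),
    ("CRP",  "mg/L",     0.0,  300.0, 0.0, 1000.0),
    ("SO2",  "%",        60.0, 100.0, 0.0, 100.0),
    ("ALB",  "g/L",      15.0, 55.0,  0.0, 100.0),
    ("HCT",  "%",        15.0, 60.0,  0.0, 100.0),
    ("PCO2", "mmHg",     15.0, 90.0,  0.0, 250.0),
    ("ALP",  "U/L",      30.0, 800.0, 0.0, 5000.0),
    ("HGB",  "g/L",      40.0, 200.0, 0.0, 300.0),
    ("K",    "mmol/L",   2.0,  7.5,   0.0, 15.0),
    ("BSD",  "mmol/L",  -10.0, 25.0, -40.0, 50.0),
    ("AC",   "0/1",      0.0,  1.0,   0.0, 1.0),
    ("GCS",  "score",    3.0,  15.0,  3.0, 15.0),
    ("DBIL", "umol/L",   0.0,  100.0, 0.0, 500.0),
    ("FIB",  "g/L",      0.5,  10.0,  0.0, 30.0),
    ("AST",  "U/L",      5.0,  1000.0, 0.0, 20000.0),
    ("PH",   "pH",       7.10, 7.55,  6.5, 8.0),
    ("BG",   "mmol/L",   1.0,  35.0,  0.0, 100.0),
]

INTERVENTION_CODES: list[str] = [
    "antibiotic",
    "vasopressor",
    "glucocorticoid",
    "ventilation",
]


def default_panel(missingness_threshold: float = 0.20) -> FeaturePanel:
    """Return the default 28-variable dynamic panel."""
    variables = [
        VariableSpec(code, unit, plo, phi, hlo, hhi)
        for code, unit, plo, phi, hlo, hhi in _DEFAULT_VARIABLES
    ]
    return FeaturePanel(variables=variables, missingness_threshold=missingness_threshold)
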