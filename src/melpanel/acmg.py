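"""Bayesian combination of ACMG/AMP evidence into seven variant classes.

The 2015 ACMG/AMP criteria assign each piece of evidence a strength
(very strong PVS, strong PS, moderate PM, supporting PP on the pathogenic
side; stand-alone BA, strong BS, supporting BP on the benign side).  The
Bayesian points formulation treats the strengths as exponentially spaced
odds of pathogenicity: supporting evidence carries odds ``O^(1/8)`` where
``O`` is the very-strong odds, moderate ``O^(2/8)``, strong ``O^(4/8)``,
very strong ``O^(8/8)``.  For an evidence profile the combined exponent is

    X = (8*nPVS + 4*nPS + 2*nPM + 1*nPP - 4*nBS - 1*nBP) / 8

and the posterior probability of pathogenicity is

    odds = O**X * prior/(1-prior);   posterior = odds / (1 + odds).

A stand-alone benign criterion (BA1) short-circuits to class benign.
The posterior is cut into seven classes: pathogenic (P), likely pathogenic
(LP), VUS-favoring pathogenic (VUS-3B), VUS, VUS-favoring benign, likely
benign (LB) and benign (B).  Defaults: prior 0.10, very-strong odds 350,
bands [0.99,1] P / [0.90,0.99) LP / [0.675,0.90) VUS-3B / [0.325,0.675) VUS
/ [0.10,0.325) VUS-favoring-benign / [0.001,0.10) LB / [0,0.001) B.  The
tripartition of the uncertain region is provisional and fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "EvidenceProfile",
    "ClassificationParams",
    "ClassificationResult",
    "combine_evidence",
    "class_from_posterior",
    "is_reportable",
    "SEVEN_CLASSES",
    "REPORTABLE_CLASSES",
]

#: the seven classes, most pathogenic first
SEVEN_CLASSES = ["P", "LP", "VUS-3B", "VUS", "VUS-favoring-benign", "LB", "B"]

#: classes counted as a positive genetic-test result
REPORTABLE_CLASSES = {"P", "LP", "VUS-3B", "VUS"}

_DEFAULT_THRESHOLDS = {
    "P": 0.99,
    "LP": 0.90,
    "VUS-3B": 0.675,
    "VUS": 0.325,
    "VUS-favoring-benign": 0.10,
    "LB": 0.001,
    # B: below the LB threshold
}


@dataclass(frozen=True)
class EvidenceProfile:
    """Counts of applied ACMG criteria by strength."""

    n_pvs: int = 0
    n_ps: int = 0
    n_pm: int = 0
    n_pp: int = 0
    n_ba: int = 0
    n_bs: int = 0
    n_bp: int = 0

    def __post_init__(self):
        for name in ("n_pvs", "n_ps", "n_pm", "n_pp", "n_ba", "n_bs", "n_bp"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def exponent(self) -> float:
        """Combined evidence exponent X (in units of very-strong evidence)."""
        return (
            8 * self.n_pvs
            + 4 * self.n_ps
            + 2 * self.n_pm
            + 1 * self.n_pp
            - 4 * self.n_bs
            - 1 * self.n_bp
        ) / 8.0


@dataclass(frozen=True)
class ClassificationParams:
    prior: float = 0.10
    odds_pvs: float = 350.0
    #: lower posterior bound of each class (half-open bands, upper-inclusive
    #: at 1.0), keyed by class label; B takes everything below the LB bound.
    class_thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))

    def __post_init__(self):
        if not 0 < self.prior < 1:
            raise ValueError(f"prior must be in (0, 1), got {self.prior}")
        if self.odds_pvs <= 1:
            raise ValueError(f"odds_pvs must exceed 1, got {self.odds_pvs}")
        labels = [c for c in SEVEN_CLASSES if c != "B"]
        if sorted(self.class_thresholds) != sorted(labels):
            raise ValueError(f"class_thresholds must list exactly {labels}")
        cuts = [self.class_thresholds[c] for c in labels]
        if any(a <= b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("class thresholds must strictly decrease from P to LB")
        if not (0 < cuts[-1] and cuts[0] < 1):
            raise ValueError("class thresholds must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class ClassificationResult:
    posterior: float
    label: str  # one of SEVEN_CLASSES


def class_from_posterior(
    p: float, params: ClassificationParams | None = None
) -> str:
    """Map a posterior probability onto the seven classes (half-open bands)."""
    if not 0 <= p <= 1:
        raise ValueError(f"posterior {p} outside [0, 1]")
    params = params or ClassificationParams()
    for label in SEVEN_CLASSES[:-1]:
        if p >= params.class_thresholds[label]:
            return label
    return "B"


def combine_evidence(
    e: EvidenceProfile, params: ClassificationParams | None = None
) -> ClassificationResult:
    """Posterior probability of pathogenicity and seven-class label.

    With no evidence the posterior equals the prior exactly.  A stand-alone
    benign criterion (``n_ba`` >= 1) forces class B regardless of any other
    evidence; the reported posterior is then 0.
    """
    params = params or ClassificationParams()
    if e.n_ba >= 1:
        return ClassificationResult(posterior=0.0, label="B")
    prior_odds = params.prior / (1.0 - params.prior)
    odds = params.odds_pvs**e.exponent * prior_odds
    posterior = odds / (1.0 + odds)
    return ClassificationResult(
        posterior=posterior, label=class_from_posterior(posterior, params)
    )


def is_reportable(label: str) -> bool:
    """True for the classes counted as a positive test (P, LP, VUS-3B, VUS)."""
    if label not in SEVEN_CLASSES:
        raise ValueError(f"unknown class label {label!r}")
    return label in REPORTABLE_CLASSES
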