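"""The three-leg mimicry-assessment algorithm.

Leg 1 (free state) compares the candidate's free-solution shape
distributions (EED and MVEE volume) against the reference GAG's.  Leg 2
(binding site) checks externally supplied docking evidence: same site, and
a docking score that holds up against the reference.  Leg 3 (bound state)
compares bound-state shape, residue-level hydrogen-bond occupancy profiles,
and total binding-free-energy intervals.  Legs are sequential: a failed leg
short-circuits and later legs are not evaluated.  Candidates are finally
ranked by (legs passed, overall score).

The source comparisons are visual (box plots) and verbal; every numeric
threshold used to operationalize "similar" is an explicit, configurable
default recorded in the report's provenance block.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import (
    EmptySeriesError,
    GagmimicError,
    InvalidEvidenceError,
    MetricMismatchError,
    MissingMetricError,
    NothingToCompareError,
    ReferenceMismatchError,
)
from .hbonds import OccupancyTable
from .energetics import EnergyDecomposition, dominant_residues


# --- summaries ------------------------------------------------------------

@dataclass
class DistributionSummary:
    """Five-number summary plus mean and sd of a metric distribution."""

    metric_name: str
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise GagmimicError("summary needs n >= 1")
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise GagmimicError(
                f"{self.metric_name}: quartiles out of order "
                f"({self.min}, {self.q1}, {self.median}, {self.q3}, {self.max})"
            )


def summary_stats(values, metric_name: str = "") -> DistributionSummary:
    """Summarize a series: linear-interpolation quartiles (position
    ``(n-1)p``), mean, and sample sd (n-1 denominator)."""
    if hasattr(values, "values") and not isinstance(values, np.ndarray):
        metric_name = metric_name or getattr(values, "metric_name", "")
        values = values.values
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise EmptySeriesError("cannot summarize an empty series")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return DistributionSummary(
        metric_name=metric_name,
        n=int(arr.size),
        min=float(arr.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(arr.max()),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )


@dataclass
class OverlapScore:
    """Interquartile-range overlap and standardized mean difference."""

    iqr_overlap: float
    standardized_mean_difference: float
    similar: bool


def _interval_jaccard(a_lo, a_hi, b_lo, b_hi) -> float:
    """|intersection| / |union| of two closed intervals (0 when disjoint).

    Two identical zero-width intervals count as fully overlapping.
    """
    inter = min(a_hi, b_hi) - max(a_lo, b_lo)
    union = max(a_hi, b_hi) - min(a_lo, b_lo)
    if union <= 0:
        return 1.0 if inter >= 0 else 0.0
    return max(inter, 0.0) / union


def overlap_index(
    a: DistributionSummary,
    b: DistributionSummary,
    overlap_threshold: float = 0.25,
    smd_threshold: float = 2.0,
) -> OverlapScore:
    """Quantitative similarity of two metric distributions.

    ``iqr_overlap`` is the Jaccard overlap of the two interquartile ranges;
    SMD is the pooled-sd standardized mean difference.  ``similar`` requires
    both iqr_overlap >= ``overlap_threshold`` and |SMD| <= ``smd_threshold``.
    """
    if a.metric_name != b.metric_name:
        raise MetricMismatchError(
            f"cannot compare {a.metric_name!r} with {b.metric_name!r}"
        )
    iqr = _interval_jaccard(a.q1, a.q3, b.q1, b.q3)
    pooled_var = (
        ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / max(a.n + b.n - 2, 1)
    )
    pooled_sd = float(np.sqrt(pooled_var))
    if pooled_sd > 0:
        smd = (a.mean - b.mean) / pooled_sd
    else:
        smd = 0.0 if a.mean == b.mean else float("inf")
    similar = (iqr >= overlap_threshold) and (abs(smd) <= smd_threshold)
    return OverlapScore(
        iqr_overlap=float(iqr),
        standardized_mean_difference=float(smd),
        similar=bool(similar),
    )


# --- evidence / thresholds ------------------------------------------------

@dataclass
class DockingEvidence:
    """Externally computed docking result for the binding-site check."""

    label: str
    score: float
    same_site_as_reference: bool
    pose_rmsd_spread: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise InvalidEvidenceError(f"{self.label}: docking score not finite")


@dataclass
class Thresholds:
    """All configurable similarity thresholds, with their defaults."""

    iqr_overlap_min: float = 0.25
    smd_max: float = 2.0
    occupancy_percent_min: float = 50.0
    occupancy_jaccard_min: float = 0.25
    mean_occupancy_diff_max: float = 25.0
    energy_top_k: int = 3
    score_ratio_min: float = 0.8


# --- verdicts -------------------------------------------------------------

class Leg(str, Enum):
    FREE_STATE = "free_state"
    BINDING_SITE = "binding_site"
    BOUND_STATE = "bound_state"


class Status(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    INCONCLUSIVE = "inconclusive"
    NOT_EVALUATED = "not_evaluated"


@dataclass
class LegVerdict:
    leg: Leg
    status: Status
    score: float
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise GagmimicError(f"leg score must be in [0, 1], got {self.score}")


def free_state_verdict(
    candidate: dict[str, DistributionSummary],
    reference: dict[str, DistributionSummary],
    thresholds: Thresholds | None = None,
) -> LegVerdict:
    """Leg 1: free-solution shape mimicry via EED and MVEE volume.

    Passes iff both metric distributions are similar under
    :func:`overlap_index`; the leg score is the mean of the two IQR
    overlaps.
    """
    th = thresholds or Thresholds()
    components = {}
    for metric in ("EED", "MVEE_volume"):
        if metric not in candidate or metric not in reference:
            raise MissingMetricError(
                f"free-state verdict needs metric {metric!r} on both sides"
            )
        components[metric] = overlap_index(
            candidate[metric], reference[metric], th.iqr_overlap_min, th.smd_max
        )
    all_similar = all(c.similar for c in components.values())
    score = float(np.mean([c.iqr_overlap for c in components.values()]))
    return LegVerdict(
        leg=Leg.FREE_STATE,
        status=Status.PASS if all_similar else Status.FAIL,
        score=min(score, 1.0),
        components=components,
    )


def binding_site_check(
    candidate: DockingEvidence | None,
    reference: DockingEvidence | None,
    thresholds: Thresholds | None = None,
) -> LegVerdict:
    """Leg 2: does the candidate bind the same site, with a docking score
    holding up against the reference?

    Passes iff ``same_site_as_reference`` and the candidate/reference score
    ratio is at least ``score_ratio_min`` (default 0.8).  Missing evidence
    on either side yields an inconclusive leg.
    """
    th = thresholds or Thresholds()
    if candidate is None or reference is None:
        return LegVerdict(Leg.BINDING_SITE, Status.INCONCLUSIVE, 0.0, {})
    if reference.score <= 0:
        raise InvalidEvidenceError(
            f"reference docking score must be positive, got {reference.score}"
        )
    ratio = candidate.score / reference.score
    clipped = float(np.clip(ratio, 0.0, 1.0))
    ok = candidate.same_site_as_reference and ratio >= th.score_ratio_min
    return LegVerdict(
        leg=Leg.BINDING_SITE,
        status=Status.PASS if ok else Status.FAIL,
        score=clipped,
        components={
            "same_site": candidate.same_site_as_reference,
            "score_ratio": float(ratio),
        },
    )


def bound_state_verdict(
    candidate_shape: dict[str, DistributionSummary],
    reference_shape: dict[str, DistributionSummary],
    candidate_occupancy: OccupancyTable | None = None,
    reference_occupancy: OccupancyTable | None = None,
    candidate_energy: EnergyDecomposition | None = None,
    reference_energy: EnergyDecomposition | None = None,
    thresholds: Thresholds | None = None,
) -> LegVerdict:
    """Leg 3: bound-state mimicry from shape, hydrogen-bond occupancy and
    binding-energy components.

    Occupancy similarity is the Jaccard of residue sets above the occupancy
    threshold (default 50%) together with the absolute difference of mean
    occupancy; energy similarity combines the overlap of the total ΔG
    (mean ± sd) intervals with the Jaccard of the top-k dominant residues.
    Absent occupancy/energy components are skipped and flagged.  The leg
    passes iff every evaluated component is similar.
    """
    th = thresholds or Thresholds()
    components: dict = {}
    scores: list[float] = []
    similar_flags: list[bool] = []

    if candidate_shape or reference_shape:
        shape_components = {}
        for metric in ("EED", "MVEE_volume"):
            if metric not in candidate_shape or metric not in reference_shape:
                raise MissingMetricError(
                    f"bound-state verdict needs metric {metric!r} on both sides"
                )
            shape_components[metric] = overlap_index(
                candidate_shape[metric],
                reference_shape[metric],
                th.iqr_overlap_min,
                th.smd_max,
            )
        shape_score = float(
            np.mean([c.iqr_overlap for c in shape_components.values()])
        )
        shape_similar = all(c.similar for c in shape_components.values())
        components["shape"] = {
            "metrics": shape_components,
            "score": shape_score,
            "similar": shape_similar,
        }
        scores.append(shape_score)
        similar_flags.append(shape_similar)

    if candidate_occupancy is not None and reference_occupancy is not None:
        set_c = candidate_occupancy.residues_above(th.occupancy_percent_min)
        set_r = reference_occupancy.residues_above(th.occupancy_percent_min)
        union = set_c | set_r
        jac = 1.0 if not union else len(set_c & set_r) / len(union)
        mean_diff = abs(
            candidate_occupancy.mean_occupancy - reference_occupancy.mean_occupancy
        )
        occ_similar = (
            jac >= th.occupancy_jaccard_min
            and mean_diff <= th.mean_occupancy_diff_max
        )
        components["occupancy"] = {
            "jaccard_above_threshold": float(jac),
            "mean_occupancy_difference": float(mean_diff),
            "score": float(jac),
            "similar": occ_similar,
        }
        scores.append(float(jac))
        similar_flags.append(occ_similar)
    elif candidate_occupancy is not None or reference_occupancy is not None:
        components["occupancy"] = {"skipped": "present on one side only"}

    if candidate_energy is not None and reference_energy is not None:
        c_lo, c_hi = candidate_energy.total_interval
        r_lo, r_hi = reference_energy.total_interval
        interval_jac = _interval_jaccard(c_lo, c_hi, r_lo, r_hi)
        top_c = set(dominant_residues(candidate_energy, th.energy_top_k))
        top_r = set(dominant_residues(reference_energy, th.energy_top_k))
        union = top_c | top_r
        top_jac = 1.0 if not union else len(top_c & top_r) / len(union)
        energy_score = float(np.mean([interval_jac, top_jac]))
        energy_similar = interval_jac > 0.0
        components["energy"] = {
            "total_interval_overlap": float(interval_jac),
            "dominant_residue_jaccard": float(top_jac),
            "score": energy_score,
            "similar": energy_similar,
        }
        scores.append(energy_score)
        similar_flags.append(energy_similar)
    elif candidate_energy is not None or reference_energy is not None:
        components["energy"] = {"skipped": "present on one side only"}

    if not scores:
        raise NothingToCompareError(
            "bound-state verdict has no evaluable components"
        )
    return LegVerdict(
        leg=Leg.BOUND_STATE,
        status=Status.PASS if all(similar_flags) else Status.FAIL,
        score=float(np.clip(np.mean(scores), 0.0, 1.0)),
        components=components,
    )


# --- reports and ranking --------------------------------------------------

class Overall(str, Enum):
    MIMIC = "mimic"
    NON_MIMIC = "non_mimic"
    INCONCLUSIVE = "inconclusive"


@dataclass
class MimicryReport:
    """Per-candidate outcome of the sequential three-leg assessment."""

    candidate: str
    reference: str
    legs: list[LegVerdict]
    overall: Overall
    overall_score: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_passed(self) -> int:
        return sum(1 for v in self.legs if v.status is Status.PASS)

    def to_dict(self) -> dict:
        def encode(obj):
            if isinstance(obj, Enum):
                return obj.value
            if isinstance(obj, OverlapScore):
                return {"__overlap__": asdict(obj)}
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "candidate": self.candidate,
            "reference": self.reference,
            "overall": self.overall.value,
            "overall_score": self.overall_score,
            "legs": [
                {
                    "leg": v.leg.value,
                    "status": v.status.value,
                    "score": v.score,
                    "components": encode(v.components),
                }
                for v in self.legs
            ],
            "provenance": encode(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MimicryReport":
        def decode(obj):
            if isinstance(obj, dict):
                if "__overlap__" in obj:
                    return OverlapScore(**obj["__overlap__"])
                return {k: decode(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [decode(v) for v in obj]
            return obj

        legs = [
            LegVerdict(
                leg=Leg(v["leg"]),
                status=Status(v["status"]),
                score=v["score"],
                components=decode(v["components"]),
            )
            for v in d["legs"]
        ]
        return cls(
            candidate=d["candidate"],
            reference=d["reference"],
            legs=legs,
            overall=Overall(d["overall"]),
            overall_score=d["overall_score"],
            provenance=decode(d.get("provenance", {})),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MimicryReport":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def compile_report(
    candidate: str,
    reference: str,
    leg_results: list[LegVerdict | None],
    provenance: dict | None = None,
) -> MimicryReport:
    """Assemble a report with sequential short-circuit semantics.

    ``leg_results`` holds the verdicts for legs 1-3 in order (None where a
    leg's inputs were unavailable → inconclusive).  Legs after the first
    failure are marked not-evaluated; overall is mimic only when all three
    legs pass, non-mimic when any completed leg fails, else inconclusive.
    """
    order = [Leg.FREE_STATE, Leg.BINDING_SITE, Leg.BOUND_STATE]
    legs: list[LegVerdict] = []
    failed = False
    for leg, verdict in zip(order, leg_results):
        if failed:
            legs.append(LegVerdict(leg, Status.NOT_EVALUATED, 0.0, {}))
            continue
        if verdict is None:
            verdict = LegVerdict(leg, Status.INCONCLUSIVE, 0.0, {})
        if verdict.leg is not leg:
            raise GagmimicError(
                f"leg verdict order mismatch: expected {leg}, got {verdict.leg}"
            )
        legs.append(verdict)
        if verdict.status is Status.FAIL:
            failed = True

    statuses = [v.status for v in legs]
    if Status.FAIL in statuses:
        overall = Overall.NON_MIMIC
    elif all(s is Status.PASS for s in statuses):
        overall = Overall.MIMIC
    else:
        overall = Overall.INCONCLUSIVE
    evaluated = [
        v.score for v in legs if v.status in (Status.PASS, Status.FAIL)
    ]
    overall_score = float(np.mean(evaluated)) if evaluated else 0.0
    return MimicryReport(
        candidate=candidate,
        reference=reference,
        legs=legs,
        overall=overall,
        overall_score=overall_score,
        provenance=provenance or {},
    )


def aggregate_over_targets(
    reports: list[MimicryReport], weights: list[float] | None = None
) -> MimicryReport:
    """Combine one candidate's reports against several protein targets.

    ``weights`` (default equal) weight each target's overall score; the
    combined overall is the worst individual outcome (a candidate mimics
    the GAG only if it does so on every weighted target).  No principled
    weighting across targets is established, so the vector is always the
    caller's explicit choice and is recorded in the provenance.
    """
    if not reports:
        raise GagmimicError("no reports to aggregate")
    labels = {r.candidate for r in reports}
    if len(labels) > 1:
        raise ReferenceMismatchError(
            f"aggregation needs one candidate, got {sorted(labels)}"
        )
    if weights is None:
        weights = [1.0] * len(reports)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(reports),) or np.any(w < 0) or w.sum() <= 0:
        raise GagmimicError("weights must be non-negative, one per report")
    w = w / w.sum()
    score = float(np.dot(w, [r.overall_score for r in reports]))
    severity = {Overall.NON_MIMIC: 2, Overall.INCONCLUSIVE: 1, Overall.MIMIC: 0}
    overall = max((r.overall for r in reports), key=lambda o: severity[o])
    return MimicryReport(
        candidate=reports[0].candidate,
        reference=" + ".join(r.reference for r in reports),
        legs=[],
        overall=overall,
        overall_score=score,
        provenance={
            "aggregated_targets": [r.reference for r in reports],
            "target_weights": w.tolist(),
        },
    )


def rank_candidates(reports: list[MimicryReport]) -> list[MimicryReport]:
    """Rank candidate reports against a shared reference.

    Order: number of passed legs (desc), then overall score (desc), then
    candidate label (asc) as a deterministic tie-break.
    """
    if not reports:
        return []
    refs = {r.reference for r in reports}
    if len(refs) > 1:
        raise ReferenceMismatchError(
            f"reports compare against different references: {sorted(refs)}"
        )
    return sorted(
        reports,
        key=lambda r: (-r.n_passed, -r.overall_score, r.candidate),
    )
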