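"""Longitudinal-cohort data model and on-disk formats.

A cohort is a collection of per-patient trajectories: aligned sequences of
covariate vectors ``x_t``, categorical treatment ids ``a_t``, outcome
vectors ``y_t`` and a binary outcome-availability mask ``m_t`` for
``t = 1..T`` (an integer visit index; calendar time is out of scope).
Treatments live in a :class:`TreatmentOntology` that groups them into
therapeutic classes (in the spirit of ATC codes) and carries an affinity
kernel ``K`` used by the embedding regularizers.

On-disk formats are deliberately plain: JSON Lines for cohorts (one object
per patient), JSON for ontologies, and a long-format CSV alternative for
cohorts exported from tabular pipelines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "Cohort",
    "TreatmentOntology",
    "SafeRegion",
    "ClinicalPriors",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_ontology",
    "write_ontology",
    "validate_cohort",
]


class CohortValidationError(ValueError):
    """A cohort, trajectory or ontology violates a structural invariant."""


# ---------------------------------------------------------------------------
@dataclass
class Trajectory:
    """One patient's aligned treatment-response record.

    Parameters
    ----------
    patient_id : str
    covariates : (T, d_x) array of observed covariates x_t.
    treatments : length-T sequence of treatment ids a_t.
    outcomes : (T, k) array of response outcomes y_t.
    outcome_mask : (T, k) binary array; 1 marks an observed outcome entry.
    stage : optional disease-stage label used by the stage-informed penalty.
    """

    patient_id: str
    covariates: np.ndarray
    treatments: list[str]
    outcomes: np.ndarray
    outcome_mask: np.ndarray
    stage: str | None = None

    def __post_init__(self) -> None:
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
        self.outcomes = np.atleast_2d(np.asarray(self.outcomes, dtype=np.float64))
        self.outcome_mask = np.atleast_2d(np.asarray(self.outcome_mask, dtype=np.float64))
        self.treatments = [str(a) for a in self.treatments]
        T = self.covariates.shape[0]
        if T < 1:
            raise CohortValidationError(f"patient {self.patient_id!r}: empty trajectory")
        for name, arr in (("outcomes", self.outcomes), ("outcome_mask", self.outcome_mask)):
            if arr.shape[0] != T:
                raise CohortValidationError(
                    f"patient {self.patient_id!r}: {name} has {arr.shape[0]} timesteps, expected {T}"
                )
        if len(self.treatments) != T:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: {len(self.treatments)} treatments, expected {T}"
            )
        if self.outcome_mask.shape != self.outcomes.shape:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: mask shape {self.outcome_mask.shape} "
                f"!= outcomes shape {self.outcomes.shape}"
            )
        if not np.isin(self.outcome_mask, (0.0, 1.0)).all():
            bad = self.outcome_mask[~np.isin(self.outcome_mask, (0.0, 1.0))][0]
            raise CohortValidationError(
                f"patient {self.patient_id!r}: mask value {bad!r} not in {{0, 1}}"
            )

    @property
    def T(self) -> int:
        return self.covariates.shape[0]

    @property
    def d_x(self) -> int:
        return self.covariates.shape[1]

    @property
    def k(self) -> int:
        return self.outcomes.shape[1]

    def check_vocabulary(self, ontology: "TreatmentOntology") -> None:
        unknown = set(self.treatments) - ontology.vocabulary
        if unknown:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: treatment ids {sorted(unknown)} "
                "not in ontology vocabulary"
            )


@dataclass
class Cohort:
    """A patient population: trajectories sharing covariate/outcome dimensions."""

    trajectories: list[Trajectory]
    d_x: int
    k: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tr in self.trajectories:
            if tr.d_x != self.d_x or tr.k != self.k:
                raise CohortValidationError(
                    f"patient {tr.patient_id!r}: dims (d_x={tr.d_x}, k={tr.k}) "
                    f"do not match cohort (d_x={self.d_x}, k={self.k})"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    def by_id(self, patient_id: str) -> Trajectory:
        for tr in self.trajectories:
            if tr.patient_id == patient_id:
                return tr
        raise KeyError(patient_id)

    def treatment_ids(self) -> set[str]:
        out: set[str] = set()
        for tr in self.trajectories:
            out.update(tr.treatments)
        return out

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort([self.trajectories[i] for i in indices], self.d_x, self.k,
                      dict(self.metadata))


# ---------------------------------------------------------------------------
class TreatmentOntology:
    """Treatment vocabulary with class structure and an affinity kernel.

    The kernel ``K(a_i, a_j)`` in [0, 1] measures knowledge-driven similarity
    between treatments.  Entries not given explicitly default to 1 for
    same-class pairs (including the diagonal) and 0 across classes, the
    minimal ATC-co-membership reading.
    """

    def __init__(
        self,
        class_of: Mapping[str, str],
        similarity_edges: Iterable[tuple[str, str]] = (),
        kernel: Mapping[tuple[str, str], float] | None = None,
    ):
        self.class_of: dict[str, str] = {str(a): str(c) for a, c in class_of.items()}
        self.vocabulary: set[str] = set(self.class_of)
        if not self.vocabulary:
            raise CohortValidationError("ontology has an empty vocabulary")
        edges: set[frozenset[str]] = set()
        for a, b in similarity_edges:
            a, b = str(a), str(b)
            for x in (a, b):
                if x not in self.vocabulary:
                    raise CohortValidationError(f"similarity edge references unknown id {x!r}")
            if a != b:
                edges.add(frozenset((a, b)))
        self.similarity_edges: set[frozenset[str]] = edges

        self._kernel: dict[frozenset[str] | str, float] = {}
        if kernel:
            sym_check: dict[tuple[str, str], float] = {}
            for (a, b), v in kernel.items():
                a, b = str(a), str(b)
                for x in (a, b):
                    if x not in self.vocabulary:
                        raise CohortValidationError(f"kernel entry references unknown id {x!r}")
                v = float(v)
                if not (0.0 <= v <= 1.0):
                    raise CohortValidationError(f"kernel value {v} for ({a!r}, {b!r}) outside [0, 1]")
                if a == b:
                    if v != 1.0:
                        raise CohortValidationError(f"kernel({a!r}, {a!r}) = {v}, must be 1")
                    continue
                if (b, a) in sym_check and sym_check[(b, a)] != v:
                    raise CohortValidationError(
                        f"asymmetric kernel: K({a!r},{b!r})={v} but K({b!r},{a!r})={sym_check[(b, a)]}"
                    )
                sym_check[(a, b)] = v
                self._kernel[frozenset((a, b))] = v

    # -- queries -------------------------------------------------------
    @property
    def classes(self) -> list[str]:
        return sorted(set(self.class_of.values()))

    def members(self, cls: str) -> list[str]:
        return sorted(a for a, c in self.class_of.items() if c == cls)

    def alpha(self, a: str) -> str:
        """Class label α(a) of a treatment."""
        try:
            return self.class_of[a]
        except KeyError:
            raise KeyError(f"unknown treatment id {a!r}") from None

    def kernel(self, a: str, b: str) -> float:
        """Affinity K(a, b); defaulted by class co-membership when absent."""
        for x in (a, b):
            if x not in self.vocabulary:
                raise KeyError(f"unknown treatment id {x!r}")
        if a == b:
            return 1.0
        key = frozenset((a, b))
        if key in self._kernel:
            return self._kernel[key]
        return 1.0 if self.class_of[a] == self.class_of[b] else 0.0

    def sorted_vocabulary(self) -> list[str]:
        return sorted(self.vocabulary)

    def to_dict(self) -> dict:
        return {
            "classes": dict(sorted(self.class_of.items())),
            "similarity_edges": sorted([sorted(e) for e in self.similarity_edges]),
            "kernel": sorted(
                [[*sorted(k), v] for k, v in self._kernel.items()],
            ),
        }


# ---------------------------------------------------------------------------
@dataclass
class SafeRegion:
    """Convex safety corridor C_safe for cumulative latent deviation.

    Either an axis-aligned box (`lower`, `upper`) or an L2 ball
    (`center`, `radius`).  Euclidean projection is closed-form for both.
    """

    kind: str  # "box" | "ball"
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    center: np.ndarray | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "box":
            self.lower = np.asarray(self.lower, dtype=np.float64)
            self.upper = np.asarray(self.upper, dtype=np.float64)
            if self.lower.shape != self.upper.shape:
                raise CohortValidationError("safe-region box bounds have different shapes")
            if np.any(self.lower > self.upper):
                raise CohortValidationError("safe-region box has lower > upper")
        elif self.kind == "ball":
            self.center = np.asarray(self.center, dtype=np.float64)
            self.radius = float(self.radius)
            if self.radius <= 0:
                raise CohortValidationError("safe-region ball radius must be > 0")
        else:
            raise CohortValidationError(f"unknown safe-region kind {self.kind!r}")

    def project(self, v: np.ndarray) -> np.ndarray:
        """Closest point of the region to `v` under the Euclidean norm."""
        v = np.asarray(v, dtype=np.float64)
        if self.kind == "box":
            return np.clip(v, self.lower, self.upper)
        d = v - self.center
        norm = float(np.linalg.norm(d))
        if norm <= self.radius:
            return v.copy()
        return self.center + d * (self.radius / norm)

    def contains(self, v: np.ndarray, atol: float = 1e-12) -> bool:
        v = np.asarray(v, dtype=np.float64)
        if self.kind == "box":
            return bool(np.all(v >= self.lower - atol) and np.all(v <= self.upper + atol))
        return float(np.linalg.norm(v - self.center)) <= self.radius + atol


_DEFAULT_WEIGHTS = {
    # the five composite-objective weights
    "lambda1": 0.1,   # ontology consistency
    "lambda2": 0.1,   # safety corridor
    "lambda3": 0.1,   # KL anchoring
    "lambda4": 0.1,   # adversarial term
    "lambda5": 0.1,   # latent temporal smoothness
    # auxiliary regularizers defined alongside the model
    "lambda_sym": 1e-2,
    "lambda_align": 1e-2,
    "lambda_smooth": 1e-2,
    "lambda_stage": 0.0,
    "lambda_drift": 0.0,
    "lambda_shift": 0.0,
    "lambda_ent": 0.0,
    "lambda_wd": 0.0,
}


@dataclass
class ClinicalPriors:
    """Clinical prior knowledge consumed by the knowledge-infusion losses.

    anchor_mean / anchor_var: diagonal-Gaussian anchoring prior π(z); either a
    single (d_z,) pair applied at every timestep or (T, d_z) per-timestep.
    safe_region: corridor for cumulative latent deviation.
    stage_curves: stage label → (T, k) expected outcome curve μ_stage(t).
    decay_rho: geometric decay ρ in (0, 1] for cumulative-influence weights.
    loss_weights: λ coefficients of the composite objective.
    margin: δ ≥ 0 of the intra-class embedding margin loss.
    """

    anchor_mean: np.ndarray | None = None
    anchor_var: np.ndarray | None = None
    safe_region: SafeRegion | None = None
    stage_curves: dict[str, np.ndarray] = field(default_factory=dict)
    decay_rho: float = 1.0
    loss_weights: dict[str, float] = field(default_factory=dict)
    margin: float = 0.1

    def __post_init__(self) -> None:
        if self.anchor_mean is not None:
            self.anchor_mean = np.asarray(self.anchor_mean, dtype=np.float64)
            self.anchor_var = np.asarray(self.anchor_var, dtype=np.float64)
            if np.any(self.anchor_var <= 0):
                raise CohortValidationError("anchor prior variance must be strictly positive")
        if not (0.0 < self.decay_rho <= 1.0):
            raise CohortValidationError("decay_rho must lie in (0, 1]")
        if self.margin < 0:
            raise CohortValidationError("margin must be >= 0")
        merged = dict(_DEFAULT_WEIGHTS)
        merged.update({k: float(v) for k, v in self.loss_weights.items()})
        for k, v in merged.items():
            if v < 0:
                raise CohortValidationError(f"loss weight {k} must be >= 0, got {v}")
        self.loss_weights = merged
        self.stage_curves = {
            s: np.atleast_2d(np.asarray(c, dtype=np.float64)) for s, c in self.stage_curves.items()
        }


# ---------------------------------------------------------------------------
# cohort I/O
def _trajectory_from_record(rec: dict, line_no: int) -> Trajectory:
    try:
        return Trajectory(
            patient_id=str(rec["patient_id"]),
            covariates=np.asarray(rec["x"], dtype=np.float64),
            treatments=list(rec["a"]),
            outcomes=np.asarray(rec["y"], dtype=np.float64),
            outcome_mask=np.asarray(rec["m"], dtype=np.float64),
            stage=rec.get("stage"),
        )
    except KeyError as exc:
        raise CohortValidationError(f"line {line_no}: missing field {exc}") from None


def read_cohort(
    path: str | Path,
    ontology: TreatmentOntology | None = None,
    d_x: int | None = None,
    k: int | None = None,
) -> Cohort:
    """Read a JSON Lines cohort file; validates every trajectory invariant.

    When `ontology` is supplied, every treatment id must belong to its
    vocabulary.  `d_x` / `k` optionally pin the expected dimensions.
    """
    path = Path(path)
    trajectories: list[Trajectory] = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortValidationError(f"{path.name} line {line_no}: malformed JSON ({exc.msg})") from None
            trajectories.append(_trajectory_from_record(rec, line_no))
    if not trajectories:
        raise CohortValidationError(f"{path.name}: no trajectories")
    d_x = trajectories[0].d_x if d_x is None else d_x
    k = trajectories[0].k if k is None else k
    cohort = Cohort(trajectories, d_x=d_x, k=k)
    if ontology is not None:
        for tr in cohort:
            tr.check_vocabulary(ontology)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for tr in cohort:
            rec = {
                "patient_id": tr.patient_id,
                "x": tr.covariates.tolist(),
                "a": list(tr.treatments),
                "y": tr.outcomes.tolist(),
                "m": tr.outcome_mask.astype(int).tolist(),
            }
            if tr.stage is not None:
                rec["stage"] = tr.stage
            fh.write(json.dumps(rec) + "\n")


def read_cohort_csv(path: str | Path, ontology: TreatmentOntology | None = None) -> Cohort:
    """Read a long-format CSV cohort (columns patient_id, t, x_*, a, y_*, m_*)."""
    df = pd.read_csv(path)
    x_cols = sorted((c for c in df.columns if c.startswith("x_")), key=lambda c: int(c[2:]))
    y_cols = sorted((c for c in df.columns if c.startswith("y_")), key=lambda c: int(c[2:]))
    m_cols = sorted((c for c in df.columns if c.startswith("m_")), key=lambda c: int(c[2:]))
    if not x_cols or not y_cols or len(m_cols) != len(y_cols):
        raise CohortValidationError("CSV cohort needs x_*, y_* and matching m_* columns")
    trajectories = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("t")
        trajectories.append(
            Trajectory(
                patient_id=str(pid),
                covariates=grp[x_cols].to_numpy(dtype=np.float64),
                treatments=[str(a) for a in grp["a"]],
                outcomes=grp[y_cols].to_numpy(dtype=np.float64),
                outcome_mask=grp[m_cols].to_numpy(dtype=np.float64),
                stage=(str(grp["stage"].iloc[0]) if "stage" in grp.columns else None),
            )
        )
    if not trajectories:
        raise CohortValidationError("CSV cohort has no rows")
    cohort = Cohort(trajectories, trajectories[0].d_x, trajectories[0].k)
    if ontology is not None:
        for tr in cohort:
            tr.check_vocabulary(ontology)
    return cohort


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    rows = []
    for tr in cohort:
        for t in range(tr.T):
            row: dict = {"patient_id": tr.patient_id, "t": t + 1, "a": tr.treatments[t]}
            row.update({f"x_{j}": tr.covariates[t, j] for j in range(tr.d_x)})
            row.update({f"y_{j}": tr.outcomes[t, j] for j in range(tr.k)})
            row.update({f"m_{j}": int(tr.outcome_mask[t, j]) for j in range(tr.k)})
            if tr.stage is not None:
                row["stage"] = tr.stage
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ontology I/O
def read_ontology(path: str | Path) -> TreatmentOntology:
    """Read a JSON ontology; symmetrizes one-sided kernel entries."""
    with Path(path).open() as fh:
        obj = json.load(fh)
    if "classes" not in obj:
        raise CohortValidationError("ontology file missing 'classes'")
    kernel: dict[tuple[str, str], float] = {}
    for entry in obj.get("kernel", []):
        a, b, v = entry
        kernel[(str(a), str(b))] = float(v)
    return TreatmentOntology(
        class_of=obj["classes"],
        similarity_edges=[tuple(e) for e in obj.get("similarity_edges", [])],
        kernel=kernel,
    )


def write_ontology(ontology: TreatmentOntology, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(ontology.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
def validate_cohort(cohort: Cohort, ontology: TreatmentOntology | None = None) -> dict:
    """Validate and summarize a cohort.

    Returns counts and per-outcome-dimension missingness rates
    (1 − mean mask).  Raises :class:`CohortValidationError` on any invariant
    violation, including treatment ids missing from the ontology.
    """
    if len(cohort) == 0:
        raise CohortValidationError("no trajectories")
    if ontology is not None:
        for tr in cohort:
            tr.check_vocabulary(ontology)
    masks = np.concatenate([tr.outcome_mask for tr in cohort], axis=0)
    return {
        "n_patients": len(cohort),
        "n_timesteps": int(masks.shape[0]),
        "d_x": cohort.d_x,
        "k": cohort.k,
        "missingness": (1.0 - masks.mean(axis=0)).tolist(),
        "treatments": sorted(cohort.treatment_ids()),
    }
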