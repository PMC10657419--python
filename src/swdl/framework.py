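"""Multi-subject orchestration: base assembly, matching, group-level
dynamics and recovery evaluation.

* Base matrices: D_q = [T_1 ... T_M] (horizontal), X_q = [S_1; ...; S_M]
  (vertical) from per-subject ssBSS components.
* Task-mode group analysis: per reference regressor, the most correlated
  atom of each subject is collected and the rank-1 SVD of the averaged
  outer-product sum gives the group atom / code pair.
* Rest-mode group analysis: element-wise mean of the absolute matched code
  rows per template.
* Recovery evaluation: absolute Pearson correlation of recovered
  components against ground truth (cTC/cSM), averaged over sources
  (mcTC/mcSM), subjects (mmcTC/mmcSM) and trials.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import abs_corr_matrix
from .hrf import CANONICAL_HRF, HrfParams, convolve_events
from .ssbss import SsbssResult
from .synthgen import GroundTruth

__all__ = [
    "BaseMatrices",
    "GroupResult",
    "EvalReport",
    "assemble_bases",
    "make_mhr",
    "match_components",
    "group_task_svd",
    "group_rest_average",
    "components_of",
    "evaluate_recovery",
    "aggregate_reports",
]


@dataclass
class BaseMatrices:
    """Multi-subject base dictionary and base sparse code."""

    D_q: np.ndarray  # N x MP
    X_q: np.ndarray  # MP x V
    provenance: list = field(default_factory=list)  # per-block subject ids

    def __post_init__(self) -> None:
        if self.D_q.shape[1] != self.X_q.shape[0]:
            raise ValueError("D_q columns must equal X_q rows")

    def block(self, m: int, P: int) -> slice:
        """Base-index slice of subject m's block (bijective with (m, p))."""
        return slice(m * P, (m + 1) * P)


@dataclass
class GroupResult:
    """Group-level dictionary / sparse code with per-subject matches."""

    D_g: np.ndarray | None  # N x R (task mode; unit-norm columns)
    X_g: np.ndarray  # R x V
    matches: np.ndarray  # M x R matched component indices j_m(r)
    match_corrs: np.ndarray  # M x R |corr| values at the match
    triplets: list = field(default_factory=list)  # (omega, delta, gamma) task mode
    mode: str = "task"


@dataclass
class EvalReport:
    """Hierarchical recovery correlations against ground truth.

    ``ctc``/``csm`` are (subjects x sources) absolute Pearson correlations;
    ``mctc``/``mcsm`` their per-subject means over sources; ``mmctc`` /
    ``mmcsm`` the means over subjects.
    """

    ctc: np.ndarray
    csm: np.ndarray
    tc_indices: np.ndarray
    sm_indices: np.ndarray

    @property
    def mctc(self) -> np.ndarray:
        return self.ctc.mean(axis=1)

    @property
    def mcsm(self) -> np.ndarray:
        return self.csm.mean(axis=1)

    @property
    def mmctc(self) -> float:
        return float(self.mctc.mean())

    @property
    def mmcsm(self) -> float:
        return float(self.mcsm.mean())

    def summary(self) -> str:
        lines = ["recovery report", "-" * 40]
        for m in range(self.ctc.shape[0]):
            lines.append(
                f"subject {m + 1}: mcTC = {self.mctc[m]:.3f}, mcSM = {self.mcsm[m]:.3f}"
            )
        lines.append(f"mean over subjects: mmcTC = {self.mmctc:.3f}, mmcSM = {self.mmcsm:.3f}")
        return "\n".join(lines)


def assemble_bases(results: list[SsbssResult]) -> BaseMatrices:
    """Concatenate ssBSS components into the base matrices.

    D_q stacks temporal sources horizontally, X_q stacks spatial sources
    vertically; blocks are ordered by subject index.
    """
    if not results:
        raise ValueError("need at least one subject result")
    Ts = [r.T for r in results]
    Ss = [r.S for r in results]
    N = Ts[0].shape[0]
    V = Ss[0].shape[1]
    for T, S in zip(Ts, Ss):
        if T.shape[0] != N or S.shape[1] != V:
            raise ValueError("all subjects must share N and V")
    return BaseMatrices(
        D_q=np.column_stack(Ts),
        X_q=np.vstack(Ss),
        provenance=[m for m, T in enumerate(Ts) for _ in range(T.shape[1])],
    )


def make_mhr(events, n_scans: int, tr: float,
             hrf: HrfParams = CANONICAL_HRF,
             conditions: list[str] | None = None) -> np.ndarray:
    """Modeled hemodynamic responses: boxcar stimuli convolved with the HRF.

    ``events`` is a table (pandas DataFrame or dict of sequences) with
    columns ``onset``, ``duration`` (seconds) and ``condition``.  One
    column per condition is returned, ordered by ``conditions`` (default:
    sorted unique labels).  Unknown labels are rejected.
    """
    import pandas as pd

    ev = pd.DataFrame(events)
    for col in ("onset", "duration", "condition"):
        if col not in ev.columns:
            raise ValueError(f"events table needs a '{col}' column")
    labels = list(ev["condition"].unique())
    if conditions is None:
        conditions = sorted(labels)
    unknown = set(labels) - set(conditions)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    window = n_scans * tr
    if ((ev["onset"] < 0) | (ev["onset"] >= window)).any():
        raise ValueError("event onsets outside the scan window")
    cols = []
    t = np.arange(n_scans) * tr
    for cond in conditions:
        sub = ev[ev["condition"] == cond]
        box = np.zeros(n_scans)
        for _, row in sub.iterrows():
            on, dur = float(row["onset"]), float(row["duration"])
            box[(t >= on) & (t < on + dur)] = 1.0
        cols.append(convolve_events(box, hrf, tr))
    return np.column_stack(cols)


def match_components(candidates: np.ndarray, references: np.ndarray):
    """For each reference row, the candidate row with highest |Pearson corr|.

    Matching is with replacement (one candidate may serve several
    references); ties break toward the lowest candidate index; zero-variance
    candidates correlate 0.  Returns (indices, |corr| values), one per
    reference.
    """
    M = abs_corr_matrix(np.asarray(candidates), np.asarray(references))
    idx = np.argmax(M, axis=0)  # argmax returns the first (lowest) maximiser
    vals = M[idx, np.arange(M.shape[1])]
    return idx, vals


def components_of(model) -> tuple[np.ndarray, np.ndarray]:
    """Extract (temporal components N x K, spatial components K x V)."""
    if isinstance(model, SsbssResult):
        return model.T, model.S
    return model.D, model.X  # SWModel / DictModel


def group_task_svd(models: list, mhr: np.ndarray) -> GroupResult:
    """Task-mode group dynamics via rank-1 SVD per reference regressor.

    For each reference r, the most correlated atom/code pair of every
    subject is collected and the leading singular triplet of
    (1/M) sum_m d_m x^m gives the group atom (unit norm) and group code.
    The sign is flipped so that corr(group atom, reference) >= 0.
    """
    Ds, Xs = zip(*(components_of(mo) for mo in models))
    N = Ds[0].shape[0]
    V = Xs[0].shape[1]
    Mn = len(models)
    R = mhr.shape[1]
    matches = np.zeros((Mn, R), dtype=int)
    corrs = np.zeros((Mn, R))
    for m, D in enumerate(Ds):
        idx, vals = match_components(D.T, mhr.T)
        matches[m] = idx
        corrs[m] = vals
    D_g = np.zeros((N, R))
    X_g = np.zeros((R, V))
    triplets = []
    for r in range(R):
        Dr = np.column_stack([Ds[m][:, matches[m, r]] for m in range(Mn)])
        Xr = np.vstack([Xs[m][matches[m, r]] for m in range(Mn)])
        if not Dr.any() or not Xr.any():
            warnings.warn(f"reference {r}: all matched pairs are zero", stacklevel=2)
            triplets.append((np.zeros(N), 0.0, np.zeros(V)))
            continue
        # (1/M) Dr Xr is a rank-<=M matrix; factor through QR for speed
        Qf, Rf = np.linalg.qr(Dr)
        W = (Rf @ Xr) / Mn
        Uw, sw, Vtw = np.linalg.svd(W, full_matrices=False)
        omega = Qf @ Uw[:, 0]
        delta = float(sw[0])
        gamma = Vtw[0]
        ref = mhr[:, r] - mhr[:, r].mean()
        if ref @ (omega - omega.mean()) < 0:
            omega = -omega
            gamma = -gamma
        D_g[:, r] = omega
        X_g[r] = delta * gamma
        triplets.append((omega, delta, gamma))
    return GroupResult(D_g=D_g, X_g=X_g, matches=matches, match_corrs=corrs,
                       triplets=triplets, mode="task")


def group_rest_average(models: list, templates: np.ndarray) -> GroupResult:
    """Rest-mode group maps: mean absolute matched code row per template."""
    _, Xs = zip(*(components_of(mo) for mo in models))
    V = Xs[0].shape[1]
    if templates.shape[1] != V:
        raise ValueError("templates and codes must share V")
    Mn = len(models)
    R = templates.shape[0]
    matches = np.zeros((Mn, R), dtype=int)
    corrs = np.zeros((Mn, R))
    for m, X in enumerate(Xs):
        idx, vals = match_components(X, templates)
        matches[m] = idx
        corrs[m] = vals
    X_g = np.zeros((R, V))
    for r in range(R):
        X_g[r] = np.mean([np.abs(Xs[m][matches[m, r]]) for m in range(Mn)], axis=0)
    return GroupResult(D_g=None, X_g=X_g, matches=matches, match_corrs=corrs,
                       mode="rest")


def evaluate_recovery(models, truth) -> EvalReport:
    """Per-subject recovery correlations against ground truth.

    ``models`` is a list of fitted per-subject models (or a single model /
    GroupResult) and ``truth`` the matching list of :class:`GroundTruth`
    (or a single group truth).  TC candidates are matched against truth
    TCs and SM candidates against truth SMs, independently, with
    replacement.
    """
    single = not isinstance(models, (list, tuple))
    model_list = [models] if single else list(models)
    truth_list = [truth] if isinstance(truth, GroundTruth) else list(truth)
    if len(truth_list) == 1 and len(model_list) > 1:
        truth_list = truth_list * len(model_list)
    if len(model_list) != len(truth_list):
        raise ValueError("models and truths must align")
    ctc, csm, tidx, sidx = [], [], [], []
    for mo, tr in zip(model_list, truth_list):
        if isinstance(mo, GroupResult):
            T = mo.D_g
            S = mo.X_g
            if T is None:
                T = np.zeros((tr.tcs.shape[0], S.shape[0]))
        else:
            T, S = components_of(mo)
        if T.shape[0] != tr.tcs.shape[0] or S.shape[1] != tr.sms.shape[1]:
            raise ValueError("component dimensions do not match the ground truth")
        it, vt = match_components(T.T, tr.tcs.T)
        isp, vs = match_components(S, tr.sms)
        ctc.append(vt)
        csm.append(vs)
        tidx.append(it)
        sidx.append(isp)
    return EvalReport(
        ctc=np.vstack(ctc), csm=np.vstack(csm),
        tc_indices=np.vstack(tidx), sm_indices=np.vstack(sidx),
    )


def aggregate_reports(reports: list[EvalReport]) -> dict:
    """Trial-level aggregation: means of mmcTC / mmcSM over trial reports."""
    if not reports:
        raise ValueError("no reports to aggregate")
    return {
        "n_trials": len(reports),
        "mmcTC": float(np.mean([r.mmctc for r in reports])),
        "mmcSM": float(np.mean([r.mmcsm for r in reports])),
        "mmcTC_sd": float(np.std([r.mmctc for r in reports], ddof=1)) if len(reports) > 1 else 0.0,
        "mmcSM_sd": float(np.std([r.mmcsm for r in reports], ddof=1)) if len(reports) > 1 else 0.0,
    }
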