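"""Residue-resolution exchange-rate optimization with replicate-based
confidence scoring.

Peptide-level HDX-MS uptake is a sum of per-residue first-order exchange
events. For a peptide with exchanging residues E (all residues except the
first two positions and prolines) the predicted corrected RFU at exposure
time t is

    RFU(t) = (1/|E|) * sum_{r in E} (1 - exp(-k_obs_r * t))

with k_obs_r = k_int_r * exp(-lnP_r): the observed rate is the intrinsic
rate slowed by the residue's protection factor P_r (reported as ln P).

Given a corrected uptake table and intrinsic rates, the optimizer
minimizes the summed squared error between predicted and measured RFUs
over the per-residue lnP vector, bounded within ``lnP_bounds``, from
multiple random initializations ("replicates"). The best-loss replicate
provides the reported rates; the scatter between replicate solutions is
summarized by the R-matrix score — the arithmetic mean of pairwise
Pearson correlations between replicate lnP vectors (negative pair
correlations clamped to zero), a value in [0, 1]. Well-constrained
peptide maps yield replicate solutions that agree (R-matrix near 1);
underdetermined maps let replicates land in different minima of equal
loss and score low.

Proteins are optimized per *subsection*: a contiguous stretch whose
peptide map is connected. :func:`propose_subsections` splits a peptide
map at coverage gaps and at junctions no peptide spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from hdx2ss._errors import ConvergenceError, ValidationError
from hdx2ss.hdx_io import KintTable, PeptideRecord, UptakeTable

logger = logging.getLogger(__name__)

#: seconds per minute — exposure times are in seconds, rates in 1/min
_SEC_PER_MIN = 60.0


def exchanging_indices(sequence: str, start: int, end: int) -> List[int]:
    """Residue indices of a peptide that contribute to its uptake signal.

    The peptide's first two positions are excluded (fast back exchange of
    the N-terminal amides during quench/digestion) along with prolines,
    which carry no amide hydrogen.
    """
    out = []
    for i in range(start + 2, end + 1):
        if sequence[i - start] != "P":
            out.append(i)
    return out


def exchanging_residues(peptide: PeptideRecord) -> List[int]:
    """Exchanging residue indices of a :class:`PeptideRecord`."""
    return exchanging_indices(peptide.sequence, peptide.start, peptide.end)


def forward_rfu(
    lnp_by_residue: Dict[int, float],
    kint: KintTable,
    sequence: str,
    start: int,
    end: int,
    time: float,
) -> float:
    """Forward model: corrected RFU of one peptide range at one exposure time.

    Mean over exchanging residues of 1 - exp(-k_obs t), with
    k_obs = k_int exp(-lnP). ``time`` is in seconds; rates in 1/min.
    """
    residues = exchanging_indices(sequence, start, end)
    if not residues:
        raise ValidationError(f"peptide {sequence} {start}-{end}: no exchanging residues")
    t_min = time / _SEC_PER_MIN
    total = 0.0
    for r in residues:
        if r not in lnp_by_residue:
            raise ValidationError(f"residue {r}: no lnP value")
        if r not in kint:
            raise ValidationError(f"residue {r}: no intrinsic rate")
        k_obs = kint[r] * np.exp(-lnp_by_residue[r])
        total += 1.0 - np.exp(-k_obs * t_min)
    return total / len(residues)


def predict_peptide_rfu(
    lnp_by_residue: Dict[int, float],
    kint: KintTable,
    peptide: PeptideRecord,
    time: float,
) -> float:
    """Forward model applied to a :class:`PeptideRecord` (time in seconds)."""
    return forward_rfu(lnp_by_residue, kint, peptide.sequence, peptide.start, peptide.end, time)


@dataclass
class SubsectionSpec:
    """A contiguous residue range with the peptides used to fit it."""

    start: int
    end: int
    peptide_ids: List[Tuple[str, int, int]]

    def validate(self, table: UptakeTable) -> None:
        by_key = {rec.key(): rec for rec in table.records}
        covered = set()
        for pid in self.peptide_ids:
            rec = by_key.get(pid)
            if rec is None:
                raise ValidationError(f"subsection {self.start}-{self.end}: unknown peptide {pid}")
            if rec.start < self.start or rec.end > self.end:
                raise ValidationError(
                    f"subsection {self.start}-{self.end}: peptide {pid} outside range"
                )
            covered.update(range(rec.start, rec.end + 1))
        span = self.end - self.start + 1
        if len(covered) < 0.8 * span:
            raise ValidationError(
                f"subsection {self.start}-{self.end}: peptides cover only "
                f"{len(covered)}/{span} residues (< 80%)"
            )


@dataclass
class OptimizerConfig:
    """Settings for the multi-start bounded lnP optimization.

    Each replicate runs a full quasi-Newton pass and then
    ``refine_passes`` rounds of windowed refinement: contiguous blocks of
    ``window`` residues are re-solved from ``window_restarts`` random
    restarts with the remaining residues held fixed, followed by a full
    polish. Setting ``refine_passes=0`` gives the plain multi-start
    quasi-Newton fit.
    """

    n_replicates: int = 10
    max_iterations: int = 2000
    seed: int = 0
    lnp_bounds: Tuple[float, float] = (0.0, 14.0)
    tolerance: float = 1e-13
    refine_passes: int = 3
    window: int = 10
    window_restarts: int = 4

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2 (pairwise correlation requires it)")
        if self.refine_passes < 0 or self.window < 2 or self.window_restarts < 0:
            raise ValidationError("refine_passes/window_restarts must be >= 0 and window >= 2")


@dataclass
class ResidueRateModel:
    """Fitted per-residue rates with per-subsection confidence scores.

    ``k_obs``/``k_int``/``lnp`` are parallel dicts keyed by residue index;
    the identity lnP = ln(k_int / k_obs) holds for every residue.
    ``subsection_of`` maps residues to subsection ids; ``r_matrix`` maps
    subsection ids to confidence scores in [0, 1]. ``peptide_errors`` are
    per-peptide mean squared residuals of the best replicate.
    """

    k_obs: Dict[int, float] = field(default_factory=dict)
    k_int: Dict[int, float] = field(default_factory=dict)
    lnp: Dict[int, float] = field(default_factory=dict)
    subsection_of: Dict[int, int] = field(default_factory=dict)
    r_matrix: Dict[int, float] = field(default_factory=dict)
    peptide_errors: Dict[Tuple[str, int, int], float] = field(default_factory=dict)
    replicates: int = 0
    best_loss: float = float("nan")
    lnp_replicates: Optional[np.ndarray] = None  # replicates x residues, fit order

    def residues(self) -> List[int]:
        return sorted(self.lnp)

    def rmatrix_of_residue(self, residue: int) -> float:
        return self.r_matrix[self.subsection_of[residue]]

    def merge(self, other: "ResidueRateModel") -> None:
        self.k_obs.update(other.k_obs)
        self.k_int.update(other.k_int)
        self.lnp.update(other.lnp)
        self.subsection_of.update(other.subsection_of)
        self.r_matrix.update(other.r_matrix)
        self.peptide_errors.update(other.peptide_errors)
        self.replicates = max(self.replicates, other.replicates)
        # total best-replicate loss across merged subsections
        if np.isnan(self.best_loss):
            self.best_loss = other.best_loss
        else:
            self.best_loss += other.best_loss


def compute_rmatrix(lnp_replicates: np.ndarray) -> float:
    """Mean pairwise Pearson correlation of replicate lnP solutions.

    Negative pair correlations are clamped to zero, so the score lies in
    [0, 1]. A replicate vector with zero variance contributes 0 to each of
    its pairs (with a warning): correlation against a constant is
    undefined and signals a degenerate fit, not agreement.
    """
    reps = np.asarray(lnp_replicates, dtype=float)
    if reps.ndim != 2 or reps.shape[0] < 2:
        raise ValidationError("need a replicates x residues matrix with >= 2 replicates")
    if reps.shape[1] < 3:
        raise ValidationError("need >= 3 residues for a meaningful correlation")
    n = reps.shape[0]
    centered = reps - reps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms < 1e-12
    if degenerate.any():
        logger.warning("%d replicate(s) have zero lnP variance; their pairs score 0", int(degenerate.sum()))
    total = 0.0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            n_pairs += 1
            if degenerate[i] or degenerate[j]:
                continue
            r = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
            total += max(0.0, r)
    return total / n_pairs


class _Design:
    """Sparse vectorization of a subsection's observations.

    Observations are (peptide, time) pairs. The membership triplets
    (obs index ``po``, residue column ``pr``, weight ``pw`` = 1/|E|)
    enumerate the exchanging residues of each observation's peptide, so a
    forward-model evaluation touches only covered entries.
    """

    def __init__(self, table: UptakeTable, kint: KintTable, spec: SubsectionSpec):
        by_key = {rec.key(): rec for rec in table.records}
        peptides = [by_key[pid] for pid in spec.peptide_ids]
        res_set = set()
        for pep in peptides:
            for r in exchanging_residues(pep):
                if r not in kint:
                    raise ValidationError(
                        f"residue {r}: exchanging in {pep.key()} but absent from k_int table"
                    )
                res_set.add(r)
        residues = sorted(res_set)
        col = {r: j for j, r in enumerate(residues)}

        po, pr, pw, times, ys, obs_pep = [], [], [], [], [], []
        o = 0
        for p_idx, pep in enumerate(peptides):
            if pep.rfu_corr is None:
                raise ValidationError(f"peptide {pep.key()}: no corrected RFUs — run correct_table first")
            ex = exchanging_residues(pep)
            if not ex:
                raise ValidationError(f"peptide {pep.key()}: no exchanging residues")
            cols = [col[r] for r in ex]
            w = 1.0 / len(ex)
            for t in sorted(pep.rfu_corr):
                po.extend([o] * len(cols))
                pr.extend(cols)
                pw.extend([w] * len(cols))
                times.append(t / _SEC_PER_MIN)
                ys.append(pep.rfu_corr[t])
                obs_pep.append(p_idx)
                o += 1
        if o < 2:
            raise ValidationError(f"subsection {spec.start}-{spec.end}: fewer than 2 observations")
        self.po = np.array(po)
        self.pr = np.array(pr)
        self.pw = np.array(pw)
        self.t_min = np.array(times)
        self.y = np.array(ys)
        self.k = np.array([kint[r] for r in residues])
        self.residues = residues
        self.peptides = peptides
        self.obs_pep = np.array(obs_pep)
        self.n_obs = o
        self.n_res = len(residues)
        # precomputed per-entry factors
        self._tk = self.t_min[self.po] * self.k[self.pr]

    def loss_and_grad(self, lnp: np.ndarray):
        e = np.exp(-self._tk * np.exp(-lnp[self.pr]))  # exp(-k_obs t) per entry
        pred = np.bincount(self.po, self.pw * (1.0 - e), minlength=self.n_obs)
        resid = pred - self.y
        loss = float(resid @ resid)
        # d pred/d lnP_r per entry: -pw * t * k_obs * e
        dentry = -self.pw * self._tk * np.exp(-lnp[self.pr]) * e
        grad = 2.0 * np.bincount(self.pr, resid[self.po] * dentry, minlength=self.n_res)
        return loss, grad

    def predictions(self, lnp: np.ndarray) -> np.ndarray:
        e = np.exp(-self._tk * np.exp(-lnp[self.pr]))
        return np.bincount(self.po, self.pw * (1.0 - e), minlength=self.n_obs)

    def window_problem(self, lnp: np.ndarray, free: np.ndarray):
        """Reduced loss/grad over only the observations touching ``free``.

        With all other residues held at ``lnp``, the loss restricted to the
        touched observations differs from the full loss by a constant, so
        minimizing it over the free coordinates minimizes the full loss.
        Returns (fg, inject) where ``fg(z)`` evaluates the reduced problem
        and ``inject(z, x)`` writes the free coordinates back into a copy
        of ``x``.
        """
        in_free = np.isin(self.pr, free)
        touched = np.unique(self.po[in_free])
        keep = np.isin(self.po, touched)
        po_l = np.searchsorted(touched, self.po[keep])
        pr_l_global = self.pr[keep]
        pw_l = self.pw[keep]
        tk_l = self._tk[keep]
        free_entry = np.isin(pr_l_global, free)
        n_obs_l = len(touched)
        # fixed residues' contribution to each touched observation
        e_fix = np.exp(-tk_l[~free_entry] * np.exp(-lnp[pr_l_global[~free_entry]]))
        fixed_part = np.bincount(
            po_l[~free_entry], pw_l[~free_entry] * (1.0 - e_fix), minlength=n_obs_l
        )
        y_l = self.y[touched]
        po_f = po_l[free_entry]
        pw_f = pw_l[free_entry]
        tk_f = tk_l[free_entry]
        col_f = np.searchsorted(free, pr_l_global[free_entry])
        n_free = len(free)

        def fg(z):
            e = np.exp(-tk_f * np.exp(-z[col_f]))
            pred = fixed_part + np.bincount(po_f, pw_f * (1.0 - e), minlength=n_obs_l)
            resid = pred - y_l
            dentry = -pw_f * tk_f * np.exp(-z[col_f]) * e
            grad = 2.0 * np.bincount(col_f, resid[po_f] * dentry, minlength=n_free)
            return float(resid @ resid), grad

        def inject(z, x):
            out = x.copy()
            out[free] = z
            return out

        return fg, inject


def _fit_one_replicate(design: _Design, cfg: "OptimizerConfig", rng: np.random.Generator):
    """One replicate: multi-phase bounded minimization.

    A full L-BFGS-B pass from a uniform-random start, then
    ``cfg.refine_passes`` rounds of windowed refinement — contiguous
    blocks of residues re-solved from random restarts with the rest held
    fixed, which lets groups of near-interchangeable residues escape
    permutation local minima — each followed by a full polish.
    Returns (lnp, loss, trajectory, converged).
    """
    lo, hi = cfg.lnp_bounds
    n = design.n_res
    bounds = [(lo, hi)] * n
    opts = {"maxiter": cfg.max_iterations, "ftol": cfg.tolerance, "gtol": 1e-9}
    traj: List[float] = []

    def full_solve(x0):
        res = minimize(design.loss_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds, options=opts)
        traj.append(float(res.fun))
        return res

    wopts = {"maxiter": 200, "ftol": cfg.tolerance, "gtol": 1e-9}

    def refine_window(x, free):
        """Best of current point + random restarts on the reduced problem."""
        fg, inject = design.window_problem(x, free)
        wbounds = [(lo, hi)] * len(free)
        res = minimize(fg, x[free], jac=True, method="L-BFGS-B", bounds=wbounds, options=wopts)
        best_z, best_wf = res.x, float(res.fun)
        for _ in range(cfg.window_restarts):
            res = minimize(
                fg, rng.uniform(lo, hi, size=len(free)), jac=True,
                method="L-BFGS-B", bounds=wbounds, options=wopts,
            )
            if res.fun < best_wf - 1e-14:
                best_z, best_wf = res.x, float(res.fun)
        return inject(best_z, x)

    res = full_solve(rng.uniform(lo, hi, size=n))
    x, best_f, converged = res.x, float(res.fun), bool(res.success)
    for p in range(cfg.refine_passes):
        # widen windows and stagger their phase across passes so
        # misassigned groups straddling earlier window edges get re-solved
        w = cfg.window + 4 * p
        stride = max(1, w // 2)
        offset = int(rng.integers(0, stride)) if p > 0 else 0
        for w0 in range(-offset, max(1, n - stride), stride):
            free = np.arange(max(0, w0), min(w0 + w, n))
            if len(free) < 2:
                continue
            x = refine_window(x, free)
        res = full_solve(x)
        if res.fun <= best_f:
            x = res.x
            converged = converged or bool(res.success)
            # stop early once a pass no longer improves meaningfully
            if best_f - res.fun < 1e-9 * max(1.0, best_f):
                best_f = float(res.fun)
                break
            best_f = float(res.fun)
    return x, best_f, traj, converged


def optimize_subsection(
    corrected: UptakeTable,
    kint: KintTable,
    spec: SubsectionSpec,
    cfg: OptimizerConfig,
    subsection_id: int = 0,
) -> ResidueRateModel:
    """Fit per-residue lnP to one subsection's corrected uptake curves.

    Runs ``cfg.n_replicates`` independent minimizations of the summed
    squared RFU error (bounded L-BFGS-B with windowed refinement, each
    from its own seeded random initialization). Returns the best-loss
    replicate's rates together with the R-matrix computed over all
    replicate solutions and per-peptide residual error scores.
    """
    spec.validate(corrected)
    design = _Design(corrected, kint, spec)

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)
    solutions = np.empty((cfg.n_replicates, design.n_res))
    losses = np.empty(cfg.n_replicates)
    trajectories = []
    any_converged = False
    for rep in range(cfg.n_replicates):
        rng = np.random.default_rng(streams[rep])
        x, f, traj, ok = _fit_one_replicate(design, cfg, rng)
        solutions[rep] = x
        losses[rep] = f
        trajectories.append(traj)
        any_converged = any_converged or ok
    if not any_converged:
        raise ConvergenceError(
            f"subsection {spec.start}-{spec.end}: no replicate converged",
            loss_trajectories=trajectories,
        )

    best = int(np.argmin(losses))
    lnp_best = solutions[best]
    score = compute_rmatrix(solutions) if design.n_res >= 3 else 0.0

    sq = (design.predictions(lnp_best) - design.y) ** 2
    pep_err = {}
    for p_idx, pep in enumerate(design.peptides):
        mask = design.obs_pep == p_idx
        pep_err[pep.key()] = float(sq[mask].mean())

    model = ResidueRateModel(
        replicates=cfg.n_replicates,
        best_loss=float(losses[best]),
        lnp_replicates=solutions,
    )
    for j, r in enumerate(design.residues):
        model.lnp[r] = float(lnp_best[j])
        model.k_int[r] = float(design.k[j])
        model.k_obs[r] = float(design.k[j] * np.exp(-lnp_best[j]))
        model.subsection_of[r] = subsection_id
    model.r_matrix[subsection_id] = score
    model.peptide_errors = pep_err
    return model


def propose_subsections(corrected: UptakeTable) -> List[SubsectionSpec]:
    """Split a peptide map into connected subsections.

    A boundary between residues j and j+1 separates two subsections if no
    peptide spans it — this covers both coverage gaps and junctions where
    adjacent peptides merely abut. Deterministic; a fully connected map
    yields a single subsection.
    """
    if not corrected.records:
        raise ValidationError("empty uptake table")
    covered = sorted(corrected.coverage())
    spans = set()
    for rec in corrected.records:
        for j in range(rec.start, rec.end):
            spans.add(j)  # peptide spans boundary j|j+1
    blocks: List[Tuple[int, int]] = []
    block_start = covered[0]
    prev = covered[0]
    for r in covered[1:]:
        if r != prev + 1 or prev not in spans:
            blocks.append((block_start, prev))
            block_start = r
        prev = r
    blocks.append((block_start, prev))

    specs = []
    for start, end in blocks:
        pids = [rec.key() for rec in corrected.records if start <= rec.start and rec.end <= end]
        if pids:
            specs.append(SubsectionSpec(start=start, end=end, peptide_ids=pids))
    return specs


def optimize_protein(
    corrected: UptakeTable,
    kint: KintTable,
    cfg: OptimizerConfig,
    subsections: Optional[Sequence[SubsectionSpec]] = None,
) -> ResidueRateModel:
    """Optimize every subsection of a protein and merge the results.

    Residues never covered by any peptide are absent from the output
    (reported as missing, never extrapolated).
    """
    if subsections is None:
        subsections = propose_subsections(corrected)
    merged = ResidueRateModel()
    for sid, spec in enumerate(subsections):
        sub_cfg = OptimizerConfig(
            n_replicates=cfg.n_replicates,
            max_iterations=cfg.max_iterations,
            seed=cfg.seed + sid,
            lnp_bounds=cfg.lnp_bounds,
            tolerance=cfg.tolerance,
            refine_passes=cfg.refine_passes,
            window=cfg.window,
            window_restarts=cfg.window_restarts,
        )
        model = optimize_subsection(corrected, kint, spec, sub_cfg, subsection_id=sid)
        merged.merge(model)
    return merged


def write_rates_csv(model: ResidueRateModel, path) -> None:
    """Write fitted rates to CSV: residue, k_obs, k_int, lnP, subsection, r_matrix."""
    import pandas as pd

    rows = []
    for r in model.residues():
        sid = model.subsection_of[r]
        rows.append(
            {
                "residue": r,
                "k_obs": model.k_obs[r],
                "k_int": model.k_int[r],
                "lnP": model.lnp[r],
                "subsection": sid,
                "r_matrix": model.r_matrix[sid],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rates_csv(path) -> ResidueRateModel:
    import pandas as pd

    df = pd.read_csv(path)
    model = ResidueRateModel()
    for _, row in df.iterrows():
        r = int(row["residue"])
        sid = int(row["subsection"])
        model.lnp[r] = float(row["lnP"])
        model.k_obs[r] = float(row["k_obs"])
        model.k_int[r] = float(row["k_int"])
        model.subsection_of[r] = sid
        model.r_matrix[sid] = float(row["r_matrix"])
    return model
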