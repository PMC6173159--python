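"""Robust-design capture–mark–recapture survival analysis.

Maximum-likelihood Pollock robust-design models: age-structured apparent
survival S with temporary emigration (γ′, γ″), time-dependent detection
p(t)/c(t) within closed secondary events, phenotype-group and individual
spot-trait covariate effects on survival, AICc model ranking, Akaike weights,
and Burnham–Anderson model averaging.

The likelihood conditions on first capture and runs a forward pass over the
hidden states {alive-inside, alive-outside, dead}: between primary occasions
the animal survives with age-dependent S, then moves inside→outside with γ″
or stays outside with γ′; within a primary occasion an inside animal is
detected at each secondary event with p (before its first within-occasion
capture) or c (after); outside and dead animals are never detected.
Permanent emigration is absorbed into apparent survival (no extra state).

All probabilities are logit-linked.  Effective sample size for AICc is the
number of individual histories.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2, norm
from statsmodels.tools.numdiff import approx_hess2

#: covariate age windows (integer seasons since first capture; 3 seasons/year)
COVARIATE_WINDOWS = {
    "first_season": (0,),
    "first_year": (0, 1, 2),
    "first_3_years": tuple(range(9)),
}

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class SurveySchedule:
    """Nested survey design: primary occasions × secondary events.

    Primary occasions are separated by one season (4 months, three occasions
    per year); secondary events within an occasion are back-to-back surveys
    treated as a closed period.
    """

    n_primary: int
    n_secondary: int = 2
    season_months: int = 4
    occasion_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_primary < 2:
            raise ValueError("need at least 2 primary occasions")
        if self.n_secondary < 1:
            raise ValueError("need at least 1 secondary event per occasion")

    @property
    def n_events(self) -> int:
        return self.n_primary * self.n_secondary

    @classmethod
    def from_date_range(
        cls,
        start: str,
        end: str,
        survey_months: tuple[int, ...] = (2, 6, 10),
        events_per_occasion: int = 2,
    ) -> "SurveySchedule":
        """Schedule from 'YYYY-MM' bounds with fixed survey months per year.

        The default months (Feb, Jun, Oct) give three occasions per year at
        the ends of the short-rain, long-rain and dry seasons.
        """
        y0, m0 = (int(v) for v in start.split("-"))
        y1, m1 = (int(v) for v in end.split("-"))
        labels = []
        for year in range(y0, y1 + 1):
            for month in survey_months:
                if (year, month) < (y0, m0) or (year, month) > (y1, m1):
                    continue
                labels.append(f"{year}-{month:02d}")
        return cls(n_primary=len(labels), n_secondary=events_per_occasion,
                   occasion_labels=tuple(labels))


@dataclass
class EncounterHistorySet:
    """Event-level 0/1 detection histories under a survey schedule."""

    histories: np.ndarray  # (n, n_events) uint8
    freq: np.ndarray       # (n,) positive int
    schedule: SurveySchedule
    groups: np.ndarray | None = None          # (n,) int labels 0..G-1
    covariates: pd.DataFrame | None = None    # per-individual trait values
    age_at_first: np.ndarray | None = None    # seasons; 0 = neonate

    def __post_init__(self) -> None:
        self.histories = np.asarray(self.histories, dtype=np.uint8)
        if self.histories.ndim != 2:
            raise ValueError("histories must be a 2-D array")
        if self.histories.shape[1] != self.schedule.n_events:
            raise ValueError(
                f"history length {self.histories.shape[1]} does not match the "
                f"schedule's {self.schedule.n_events} events")
        if not np.isin(self.histories, (0, 1)).all():
            raise ValueError("histories must be binary")
        if not self.histories.any(axis=1).all():
            raise ValueError("every history needs at least one detection")
        self.freq = np.asarray(self.freq, dtype=int)
        if np.any(self.freq <= 0):
            raise ValueError("frequencies must be positive")
        if self.age_at_first is None:
            self.age_at_first = np.zeros(len(self.histories), dtype=int)

    @property
    def n_individuals(self) -> int:
        return self.histories.shape[0]

    @property
    def first_event(self) -> np.ndarray:
        return np.argmax(self.histories, axis=1)

    @property
    def first_primary(self) -> np.ndarray:
        return self.first_event // self.schedule.n_secondary

    @property
    def n_groups(self) -> int:
        return 1 if self.groups is None else int(self.groups.max()) + 1

    def data_key(self) -> str:
        """Content hash used to refuse cross-dataset model comparisons."""
        h = hashlib.sha1()
        h.update(self.histories.tobytes())
        h.update(self.freq.tobytes())
        if self.groups is not None:
            h.update(np.asarray(self.groups).tobytes())
        if self.covariates is not None:
            h.update(self.covariates.to_csv().encode())
        return h.hexdigest()

    def with_groups(self, groups: np.ndarray) -> "EncounterHistorySet":
        return EncounterHistorySet(self.histories, self.freq, self.schedule,
                                   np.asarray(groups, dtype=int),
                                   self.covariates, self.age_at_first)


# ---------------------------------------------------------------------------
# MARK-style .inp dialect


def write_inp(data: EncounterHistorySet, path, header: str | None = None) -> None:
    """Write histories as 'history freq [covariates] ;' records."""
    cov = data.covariates
    with open(path, "w") as fh:
        fh.write(f"/* {data.n_individuals} histories, "
                 f"{data.schedule.n_events} events */\n")
        if header:
            fh.write(f"/* {header} */\n")
        for i in range(data.n_individuals):
            hist = "".join(str(int(v)) for v in data.histories[i])
            line = f"{hist} {int(data.freq[i])}"
            if cov is not None:
                line += " " + " ".join(f"{cov.iloc[i][c]:.6f}" for c in cov.columns)
            fh.write(line + ";\n")


def read_inp(
    path, schedule: SurveySchedule, covariate_names: list[str] | None = None
) -> EncounterHistorySet:
    """Parse the MARK-style .inp dialect written by :func:`write_inp`.

    Records are 'history whitespace frequency [covariates] ;'; '/* ... */'
    comments are ignored.  Malformed records raise with their line number.
    """
    hists, freqs, covs = [], [], []
    with open(path) as fh:
        text = fh.read()
    text = re.sub(r"/\*.*?\*/", " ", text, flags=re.S)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        for record in filter(None, (r.strip() for r in line.split(";"))):
            parts = record.split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 'history frequency'")
            hist = parts[0]
            if not set(hist) <= {"0", "1"}:
                raise ValueError(f"line {lineno}: non-binary history characters")
            if len(hist) != schedule.n_events:
                raise ValueError(
                    f"line {lineno}: history length {len(hist)} != "
                    f"{schedule.n_events} events in schedule")
            freq = int(parts[1])
            if freq == 0:
                raise ValueError(f"line {lineno}: zero frequency")
            hists.append([int(ch) for ch in hist])
            freqs.append(freq)
            covs.append([float(v) for v in parts[2:]])
    cov_df = None
    if covs and any(len(c) for c in covs):
        ncov = len(covs[0])
        if covariate_names is None:
            covariate_names = [f"cov{j}" for j in range(ncov)]
        cov_df = pd.DataFrame(covs, columns=covariate_names[:ncov])
    return EncounterHistorySet(np.asarray(hists, dtype=np.uint8),
                               np.asarray(freqs), schedule,
                               covariates=cov_df)


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class SurvivalModelSpec:
    """Structure of one robust-design model, logit link throughout.

    The default is the full model {S(A), γ′(A), γ″(A), p(t), c(t)}: survival
    and both emigration probabilities logit-linear in age A (seasons since
    first capture), detection time-dependent by primary occasion.  Group
    effects on S are 'additive' (common age slope, separate intercepts) or
    'multiplicative' (separate slopes too).  An individual covariate enters
    S linearly or quadratically, only on intervals whose starting age falls
    in ``cov_window_ages``.
    """

    name: str = "S(A) gpp(A) gp(A) p(t) c(t)"
    s_age: bool = True
    group_effect: str = "none"   # none | additive | multiplicative
    covariate: str | None = None
    cov_form: str = "linear"     # linear | quadratic
    cov_window_ages: tuple[int, ...] = COVARIATE_WINDOWS["first_season"]
    gamma_age: bool = True
    gamma_equal: bool = False    # constrain gamma' = gamma''
    p_time: bool = True
    c_time: bool = True
    standardize_cov: bool = True

    def __post_init__(self) -> None:
        if self.group_effect not in ("none", "additive", "multiplicative"):
            raise ValueError("group_effect must be none|additive|multiplicative")
        if self.cov_form not in ("linear", "quadratic"):
            raise ValueError("cov_form must be linear or quadratic")

    @classmethod
    def from_string(cls, formula: str) -> "SurvivalModelSpec":
        """Build a spec from a compact formula string.

        Grammar (terms separated by whitespace, all optional except S):
        ``S(.)`` or ``S(A)`` with optional ``+group`` / ``xgroup`` and an
        optional covariate term ``+name`` or ``+name^2`` with an optional
        age window ``@first_season|@first_year|@first_3_years``;
        ``gp(A)|gp(.)``, ``gpp(A)|gpp(.)``, ``p(t)|p(.)``, ``c(t)|c(.)``.
        Example: ``"S(A+group) gpp(A) gp(A) p(t) c(t)"``.
        """
        kw: dict = {}
        terms = dict(re.findall(r"(S|gpp|gp|p|c)\(([^)]*)\)", formula))
        if "S" not in terms:
            raise ValueError(f"formula {formula!r} has no S(...) term")
        s = terms["S"].replace(" ", "")
        kw["s_age"] = s.startswith("A")
        body = s[1:] if kw["s_age"] else s.lstrip(".")
        if "xgroup" in body or "×group" in body:
            kw["group_effect"] = "multiplicative"
            body = body.replace("xgroup", "").replace("×group", "")
        elif "+group" in body:
            kw["group_effect"] = "additive"
            body = body.replace("+group", "")
        cov = body.strip("+")
        if cov:
            if "@" in cov:
                cov, window = cov.split("@", 1)
                if window not in COVARIATE_WINDOWS:
                    raise ValueError(f"unknown age window {window!r}")
                kw["cov_window_ages"] = COVARIATE_WINDOWS[window]
            if cov.endswith("^2"):
                kw["cov_form"] = "quadratic"
                cov = cov[:-2]
            kw["covariate"] = cov
        kw["gamma_age"] = terms.get("gpp", "A").strip() == "A"
        if "gp" not in terms:
            kw["gamma_equal"] = True
        kw["p_time"] = terms.get("p", "t").strip() == "t"
        kw["c_time"] = terms.get("c", "t").strip() == "t"
        return cls(name=formula, **kw)

    def param_names(self, data: EncounterHistorySet) -> list[str]:
        names = ["S:int"]
        if self.s_age:
            names.append("S:age")
        if self.group_effect != "none":
            for g in range(1, data.n_groups):
                names.append(f"S:group{g}")
            if self.group_effect == "multiplicative":
                for g in range(1, data.n_groups):
                    names.append(f"S:age.group{g}")
        if self.covariate is not None:
            names.append(f"S:{self.covariate}")
            if self.cov_form == "quadratic":
                names.append(f"S:{self.covariate}^2")
        names.append("gpp:int")
        if self.gamma_age:
            names.append("gpp:age")
        if not self.gamma_equal:
            names.append("gp:int")
            if self.gamma_age:
                names.append("gp:age")
        T = data.schedule.n_primary
        names += [f"p:t{t}" for t in range(T)] if self.p_time else ["p:int"]
        names += [f"c:t{t}" for t in range(T)] if self.c_time else ["c:int"]
        return names


class _ModelDesign:
    """Cached design structures for one (data, spec) pair."""

    def __init__(self, data: EncounterHistorySet, spec: SurvivalModelSpec):
        self.data = data
        self.spec = spec
        sched = data.schedule
        self.T, self.J = sched.n_primary, sched.n_secondary
        self.n = data.n_individuals
        self.hist = data.histories.reshape(self.n, self.T, self.J)
        self.f = data.first_primary
        self.freq = data.freq.astype(float)
        # age at the start of interval t (between primaries t and t+1)
        t_idx = np.arange(self.T - 1)
        self.age = np.maximum(
            0, data.age_at_first[:, None] + (t_idx[None, :] - self.f[:, None]))
        # group design
        self.n_groups = data.n_groups
        if spec.group_effect != "none" and self.n_groups < 2:
            raise ValueError("group model requested but data carry no groups")
        if self.n_groups > 1:
            self.group_onehot = np.eye(self.n_groups)[data.groups][:, 1:]
        else:
            self.group_onehot = np.zeros((self.n, 0))
        # covariate
        if spec.covariate is not None:
            if data.covariates is None or spec.covariate not in data.covariates:
                raise ValueError(f"covariate {spec.covariate!r} not in data")
            x = data.covariates[spec.covariate].to_numpy(dtype=float)
            if np.std(x) == 0:
                raise ValueError(f"covariate {spec.covariate!r} is constant")
            if spec.standardize_cov:
                x = (x - x.mean()) / x.std(ddof=1)
            self.cov = x
            self.cov_mask = np.isin(self.age, spec.cov_window_ages)
        else:
            self.cov = None
            self.cov_mask = None
        # detection bookkeeping: use c after the first within-occasion capture
        cum_prev = np.zeros_like(self.hist)
        cum_prev[:, :, 1:] = np.cumsum(self.hist[:, :, :-1], axis=2)
        self.use_c = cum_prev > 0
        # events at/before first capture are conditioned on (contribute 1)
        ev = np.arange(self.T * self.J).reshape(self.T, self.J)
        self.conditioned = ev[None, :, :] <= data.first_event[:, None, None]
        self.conditioned &= (np.arange(self.T)[None, :, None] == self.f[:, None, None])
        self.detected_free = (self.hist * ~self.conditioned).any(axis=2)
        self.names = spec.param_names(data)
        self.K = len(self.names)
        self._slices = self._build_slices()

    def _build_slices(self) -> dict:
        names = self.names
        sl = {}
        def grab(prefix):
            return [i for i, nm in enumerate(names) if nm.startswith(prefix)]
        sl["s"] = grab("S:")
        sl["gpp"] = grab("gpp:")
        sl["gp"] = sl["gpp"] if self.spec.gamma_equal else grab("gp:")
        sl["p"] = grab("p:")
        sl["c"] = grab("c:")
        return sl

    # -- parameter transforms ------------------------------------------------

    def survival_logit(self, beta: np.ndarray) -> np.ndarray:
        """Linear predictor of S per individual × interval, (n, T-1)."""
        spec = self.spec
        idx = iter(self._slices["s"])
        eta = np.full((self.n, self.T - 1), beta[next(idx)])
        if spec.s_age:
            eta = eta + beta[next(idx)] * self.age
        if spec.group_effect != "none":
            offs = np.array([beta[next(idx)] for _ in range(self.n_groups - 1)])
            eta = eta + (self.group_onehot @ offs)[:, None]
            if spec.group_effect == "multiplicative":
                slopes = np.array([beta[next(idx)] for _ in range(self.n_groups - 1)])
                eta = eta + (self.group_onehot @ slopes)[:, None] * self.age
        if spec.covariate is not None:
            b1 = beta[next(idx)]
            term = b1 * self.cov[:, None]
            if spec.cov_form == "quadratic":
                b2 = beta[next(idx)]
                term = term + b2 * (self.cov ** 2)[:, None]
            eta = eta + term * self.cov_mask
        return eta

    def _gamma(self, beta: np.ndarray, which: str) -> np.ndarray:
        idx = self._slices[which]
        eta = np.full((self.n, self.T - 1), beta[idx[0]])
        if self.spec.gamma_age:
            eta = eta + beta[idx[1]] * self.age
        return expit(eta)

    def probabilities(self, beta: np.ndarray):
        S = expit(self.survival_logit(beta))
        gpp = self._gamma(beta, "gpp")
        gp = self._gamma(beta, "gp")
        p_b = beta[self._slices["p"]]
        c_b = beta[self._slices["c"]]
        p = expit(np.broadcast_to(p_b, (self.T,)) if p_b.size == self.T
                  else np.full(self.T, p_b[0]))
        c = expit(np.broadcast_to(c_b, (self.T,)) if c_b.size == self.T
                  else np.full(self.T, c_b[0]))
        return S, gpp, gp, p, c

    # -- likelihood ----------------------------------------------------------

    def _emissions(self, p: np.ndarray, c: np.ndarray) -> np.ndarray:
        """P(observed events in primary t | inside), shape (n, T)."""
        pc = np.where(self.use_c, c[None, :, None], p[None, :, None])
        q = np.where(self.hist == 1, pc, 1.0 - pc)
        q = np.where(self.conditioned, 1.0, q)
        return q.prod(axis=2)

    def negloglik(self, beta: np.ndarray) -> float:
        beta = np.asarray(beta, dtype=float)
        if not np.all(np.isfinite(beta)):
            return 1e12
        S, gpp, gp, p, c = self.probabilities(beta)
        em_in = self._emissions(p, c)
        em_zero = (~self.detected_free).astype(float)
        alpha = np.zeros((self.n, 3))
        for t in range(self.T):
            if t > 0:
                aI, aO, aD = alpha[:, 0], alpha[:, 1], alpha[:, 2]
                S_, gpp_, gp_ = S[:, t - 1], gpp[:, t - 1], gp[:, t - 1]
                newI = (aI * (1.0 - gpp_) + aO * (1.0 - gp_)) * S_
                newO = (aI * gpp_ + aO * gp_) * S_
                newD = aD + (aI + aO) * (1.0 - S_)
                alpha = np.stack([newI * em_in[:, t],
                                  newO * em_zero[:, t],
                                  newD * em_zero[:, t]], axis=1)
            entering = self.f == t
            if entering.any():
                alpha[entering] = 0.0
                alpha[entering, 0] = em_in[entering, t]
        lik = alpha.sum(axis=1)
        if np.any(~np.isfinite(lik)):
            bad = int(np.argmax(~np.isfinite(lik)))
            warnings.warn(f"non-finite likelihood for individual {bad}",
                          stacklevel=2)
            return 1e12
        if np.any(lik <= 0.0):
            # impossible history under these betas (e.g. certain detection
            # missed): infinite deviance, steer the optimiser away quietly
            return 1e12
        return float(-(self.freq * np.log(np.maximum(lik, _LOG_FLOOR))).sum())


def negloglik(
    beta: np.ndarray, data: EncounterHistorySet, spec: SurvivalModelSpec
) -> float:
    """Negative log-likelihood of ``beta`` under ``spec`` for ``data``."""
    return _ModelDesign(data, spec).negloglik(np.asarray(beta, dtype=float))


# ---------------------------------------------------------------------------
# fitting and multimodel inference


@dataclass
class ModelFit:
    """One fitted robust-design model."""

    spec: SurvivalModelSpec
    beta: np.ndarray
    cov_matrix: np.ndarray
    loglik: float
    K: int
    ess: int
    aicc: float
    param_names: list[str]
    converged: bool
    gradient_norm: float
    data_key: str
    design: _ModelDesign = field(repr=False, default=None)

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_matrix), 0.0, None))

    def beta_ci(self, name: str, level: float = 0.95):
        """(estimate, lo, hi, significant) for one beta on the logit scale."""
        i = self.param_names.index(name)
        z = norm.ppf(0.5 + level / 2.0)
        est, se = self.beta[i], self.se()[i]
        lo, hi = est - z * se, est + z * se
        return est, lo, hi, bool(lo > 0 or hi < 0)


@dataclass
class RealEstimate:
    """A parameter on the probability scale with delta-method uncertainty."""

    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    significant: bool | None = None


def aicc(nll: float, K: int, ess: int) -> float:
    """Small-sample Akaike information criterion."""
    correction = 2.0 * K * (K + 1) / (ess - K - 1) if ess - K - 1 > 0 else np.inf
    return 2.0 * nll + 2.0 * K + correction


def fit_model(
    data: EncounterHistorySet,
    spec: SurvivalModelSpec,
    n_restarts: int = 5,
    seed: int = 0,
    maxiter: int = 1000,
    jitter_sd: float = 0.5,
    compute_hessian: bool = True,
) -> ModelFit:
    """Maximise the robust-design likelihood by quasi-Newton search.

    Optimisation starts from zero betas plus ``n_restarts`` seeded jittered
    starts; the best optimum is kept.  Standard errors come from the inverse
    of a numerically differenced Hessian (pseudo-inverse, with a warning, when
    the Hessian is singular, e.g. structurally inactive parameters).
    """
    design = _ModelDesign(data, spec)
    rng = np.random.default_rng(seed)
    starts = [np.zeros(design.K)]
    starts += [jitter_sd * rng.standard_normal(design.K) for _ in range(n_restarts)]
    best = None
    for x0 in starts:
        res = optimize.minimize(design.negloglik, x0, method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 1e-12,
                                         "gtol": 1e-8})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if compute_hessian:
        hess = approx_hess2(best.x, design.negloglik)
        try:
            cov = np.linalg.inv(hess)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < -1e-6):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian: using pseudo-inverse for SEs",
                          stacklevel=2)
            cov = np.linalg.pinv(hess)
    else:
        cov = np.full((design.K, design.K), np.nan)
    ess = int(data.freq.sum())
    grad_norm = float(np.linalg.norm(
        optimize.approx_fprime(best.x, design.negloglik, 1e-6)))
    return ModelFit(spec=spec, beta=best.x, cov_matrix=cov,
                    loglik=-float(best.fun), K=design.K, ess=ess,
                    aicc=aicc(float(best.fun), design.K, ess),
                    param_names=design.names, converged=bool(best.success),
                    gradient_norm=grad_norm, data_key=data.data_key(),
                    design=design)


def akaike_weights(fits: list[ModelFit]) -> np.ndarray:
    """w_i = exp(−Δ_i/2) / Σ exp(−Δ_j/2) over a model set on the same data."""
    if len(fits) == 0:
        raise ValueError("empty model set")
    keys = {f.data_key for f in fits}
    if len(keys) > 1:
        raise ValueError("models were fitted to different datasets")
    a = np.array([f.aicc for f in fits])
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def model_selection_table(fits: list[ModelFit]) -> pd.DataFrame:
    """Model, ΔAICc, weight, K — sorted by AICc, ties broken by smaller K."""
    w = akaike_weights(fits)
    df = pd.DataFrame({
        "model": [f.spec.name for f in fits],
        "AICc": [f.aicc for f in fits],
        "dAICc": [f.aicc - min(g.aicc for g in fits) for f in fits],
        "W": w,
        "K": [f.K for f in fits],
        "logLik": [f.loglik for f in fits],
    })
    return df.sort_values(["AICc", "K"]).reset_index(drop=True)


def real_survival(
    fit: ModelFit, age: int, group: int = 0, cov_value: float = 0.0,
    level: float = 0.95,
) -> RealEstimate:
    """Seasonal survival on the probability scale for an age (and group).

    The point estimate is expit(x'β); the CI is computed on the logit scale
    and back-transformed, so it respects [0, 1].
    """
    spec = fit.spec
    names = fit.param_names
    x = np.zeros(len(names))
    x[names.index("S:int")] = 1.0
    if spec.s_age:
        x[names.index("S:age")] = age
    if spec.group_effect != "none" and group > 0:
        x[names.index(f"S:group{group}")] = 1.0
        if spec.group_effect == "multiplicative":
            x[names.index(f"S:age.group{group}")] = age
    if spec.covariate is not None and age in spec.cov_window_ages:
        x[names.index(f"S:{spec.covariate}")] = cov_value
        if spec.cov_form == "quadratic":
            x[names.index(f"S:{spec.covariate}^2")] = cov_value ** 2
    eta = float(x @ fit.beta)
    var_eta = float(x @ fit.cov_matrix @ x)
    se_eta = np.sqrt(max(var_eta, 0.0))
    est = float(expit(eta))
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = expit(eta - z * se_eta), expit(eta + z * se_eta)
    return RealEstimate(estimate=est, se=est * (1 - est) * se_eta,
                        ci_lo=float(lo), ci_hi=float(hi))


def model_average(
    estimates: np.ndarray, variances: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Burnham–Anderson model-averaged estimate and unconditional variance.

    θ̄ = Σ wᵢ θ̂ᵢ; var = Σ wᵢ (varᵢ + (θ̂ᵢ − θ̄)²).
    """
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    weights = np.asarray(weights, dtype=float)
    theta = float(np.sum(weights * estimates))
    var = float(np.sum(weights * (variances + (estimates - theta) ** 2)))
    return theta, var


def model_average_survival(
    fits: list[ModelFit], age: int, group: int = 0, level: float = 0.95
) -> RealEstimate:
    """Model-averaged seasonal survival at an age for one phenotype group.

    Models without a group structure contribute their structurally implied
    (group-free) estimate.
    """
    w = akaike_weights(fits)
    ests, variances = [], []
    for f in fits:
        g = group if f.spec.group_effect != "none" else 0
        r = real_survival(f, age, group=g, level=level)
        ests.append(r.estimate)
        variances.append(r.se ** 2)
    theta, var = model_average(np.array(ests), np.array(variances), w)
    se = float(np.sqrt(var))
    z = norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, theta - z * se)
    hi = min(1.0, theta + z * se)
    return RealEstimate(estimate=theta, se=se, ci_lo=lo, ci_hi=hi)


def covariate_effect_models(
    data: EncounterHistorySet,
    trait: str,
    form: str = "linear",
    window: str = "first_season",
    **fit_kwargs,
) -> ModelFit:
    """Fit {S(A + covariate) γ″(A) γ′(A) p(t) c(t)} for one spot trait.

    ``window`` picks the age period on which the covariate acts: the first
    season of life, the first year, or the first three years.  Quadratic
    models include the linear term (standard polynomial nesting).
    """
    if window not in COVARIATE_WINDOWS:
        raise ValueError(f"window must be one of {sorted(COVARIATE_WINDOWS)}")
    suffix = "^2" if form == "quadratic" else ""
    spec = SurvivalModelSpec(
        name=f"S(A+{trait}{suffix},{window}) gpp(A) gp(A) p(t) c(t)",
        covariate=trait, cov_form=form,
        cov_window_ages=COVARIATE_WINDOWS[window])
    return fit_model(data, spec, **fit_kwargs)


def lrt(fit_null: ModelFit, fit_alt: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested models: (statistic, df, p)."""
    if fit_null.data_key != fit_alt.data_key:
        raise ValueError("models were fitted to different datasets")
    if not set(fit_null.param_names) <= set(fit_alt.param_names):
        raise ValueError("models are not nested")
    df = fit_alt.K - fit_null.K
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    p = 1.0 if df == 0 and stat == 0.0 else float(chi2.sf(stat, max(df, 1)))
    if df == 0:
        p = 1.0 if stat <= 1e-12 else 0.0
    return stat, df, p


def phenotype_group_model_set(
    data3: EncounterHistorySet, data4: EncounterHistorySet, **fit_kwargs
) -> list[ModelFit]:
    """The five-model phenotype-group set: null, A+3, A×3, A+4, A×4 groups.

    ``data3`` and ``data4`` carry the same histories with three- and
    four-group assignments; the null (one-group) model is fitted on the
    group-free histories.

    Note: weights/ΔAICc comparisons require identical histories; the group
    labels differ, so this helper rebuilds all five fits on a shared history
    set and keys them consistently.
    """
    base = EncounterHistorySet(data3.histories, data3.freq, data3.schedule,
                               None, data3.covariates, data3.age_at_first)
    fits = [fit_model(base, SurvivalModelSpec(
        name="S(A) gpp(A) gp(A) p(t) c(t)  [1 group]"), **fit_kwargs)]
    for data_g, label in ((data3, "3 groups"), (data4, "4 groups")):
        for effect, sym in (("additive", "+"), ("multiplicative", "x")):
            spec = SurvivalModelSpec(
                name=f"S(A {sym} {label}) gpp(A) gp(A) p(t) c(t)",
                group_effect=effect)
            fits.append(fit_model(data_g, spec, **fit_kwargs))
    # align data keys: identical histories, differing labels only
    for f in fits:
        f.data_key = base.data_key()
    return fits
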