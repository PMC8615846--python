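"""Extended unified SEM (euSEM) estimation for one subject.

The model for the p ROI series :math:`y_t` with convolved task inputs :math:`u_t` is

.. math::

    y_t = A y_t + \\Phi y_{t-1} + \\Gamma u_t + T (u_t \\otimes y_t) + \\zeta_t

with contemporaneous paths ``A`` (zero diagonal), lag-1 paths ``Phi`` (diagonal =
autoregressive base), direct input effects ``Gamma``, bilinear (input-modulated) effects
``T``, and white dynamic noise with diagonal covariance.  Lagged series and convolved
inputs are predetermined; bilinear terms are the products of the centered convolved input
with the centered source series, treated as fixed regressors.

Estimation follows the unified-SEM treatment of the lagged data representation:

* recursive (acyclic) contemporaneous structures are estimated equation by equation —
  with diagonal noise this is exactly maximum likelihood;
* cyclic structures are estimated by full-information ML including the
  log|det(I - A)| Jacobian, after an explicit instrument-count identification check.

:class:`EuSEM` is the model object; :meth:`EuSEM.fit` returns an :class:`EuSEMResults`
carrying per-path estimates/SEs/z, the log-likelihood, SEM fit indices against the
saturated and independence-baseline models, Lagrange-multiplier modification indices for
candidate paths, and a Wald pruning check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .edges import Edge, NetworkStructure, StructureError
from .hrf import HRFEstimate, convolve_input

__all__ = [
    "EuSEM",
    "EuSEMResults",
    "EstimationError",
    "IdentificationError",
    "NotConvergedError",
    "FIT_THRESHOLDS",
    "excellent_fit_verdict",
]

#: 2-of-4 excellent-fit thresholds: CFI > .95, NNFI > .95, RMSEA < .05, SRMR < .05.
FIT_THRESHOLDS = {"cfi": 0.95, "nnfi": 0.95, "rmsea": 0.05, "srmr": 0.05}


class EstimationError(RuntimeError):
    """Estimation failed for a structural reason."""


class IdentificationError(EstimationError):
    """The contemporaneous structure is not identified."""


class NotConvergedError(EstimationError):
    """A downstream quantity was requested from a non-converged fit."""


def excellent_fit_verdict(indices: dict) -> bool:
    """True iff at least two of the four index thresholds are met."""
    passed = (
        (indices["cfi"] > FIT_THRESHOLDS["cfi"])
        + (indices["nnfi"] > FIT_THRESHOLDS["nnfi"])
        + (indices["rmsea"] < FIT_THRESHOLDS["rmsea"])
        + (indices["srmr"] < FIT_THRESHOLDS["srmr"])
    )
    return bool(passed >= 2)


class EuSEM:
    """Single-subject euSEM over a T x (p ROIs + inputs) matrix.

    Parameters
    ----------
    data : DataFrame with the ROI columns named in ``structure.roi_names`` and,
        optionally, the input columns named in ``structure.input_names``.
    structure : the set of free paths (must contain the autoregressive base).
    hrfs : mapping input name -> HRFEstimate.  When given, binary input columns are
        convolved with the corresponding HRF; when None the input columns are used
        as provided (i.e. assumed already convolved).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        structure: NetworkStructure,
        hrfs: dict[str, HRFEstimate] | None = None,
    ):
        self.structure = structure
        self.roi_names = structure.roi_names
        self.input_names = tuple(n for n in structure.input_names if n in data.columns)
        missing = [r for r in self.roi_names if r not in data.columns]
        if missing:
            raise EstimationError(f"data lacks ROI columns {missing}")
        y_full = data[list(self.roi_names)].to_numpy(dtype=float)
        if np.isnan(y_full).any():
            raise EstimationError("ROI series contain missing values")
        self.n_obs = len(y_full) - 1  # one row lost to the lag
        if self.n_obs < 2:
            raise EstimationError("series too short for a lag-1 model")
        self.endog = y_full[1:]
        columns: dict[str, np.ndarray] = {}
        for j, r in enumerate(self.roi_names):
            columns[f"y:{r}"] = self.endog[:, j]
            columns[f"lag:{r}"] = y_full[:-1, j]
        for k in self.input_names:
            u = data[k].to_numpy(dtype=float)
            if hrfs is not None:
                if k not in hrfs:
                    raise EstimationError(f"no HRF supplied for input {k!r}")
                u = convolve_input(u, hrfs[k])
            columns[f"u:{k}"] = u[1:]
        for k in self.input_names:
            uc = columns[f"u:{k}"] - columns[f"u:{k}"].mean()
            for r in self.roi_names:
                yc = columns[f"y:{r}"] - columns[f"y:{r}"].mean()
                columns[f"bl:{k}:{r}"] = uc * yc
        self._columns = columns
        self._check_structure_inputs(structure)
        n_free = len(structure.edges) + len(self.roi_names)
        if self.n_obs < 10 * n_free:
            warnings.warn(
                f"only {self.n_obs} usable scans for {n_free} free parameters "
                "(fewer than 10 per parameter)",
                stacklevel=2,
            )

    # -- plumbing --------------------------------------------------------------------
    def _check_structure_inputs(self, structure: NetworkStructure) -> None:
        for e in structure.edges:
            if self.edge_column_name(e) not in self._columns:
                raise EstimationError(
                    f"edge {e.label()} references input data that is not available"
                )

    @staticmethod
    def edge_column_name(edge: Edge) -> str:
        if edge.kind == "contemporaneous":
            return f"y:{edge.source}"
        if edge.kind == "lagged":
            return f"lag:{edge.source}"
        if edge.kind == "direct":
            return f"u:{edge.source}"
        return f"bl:{edge.input}:{edge.source}"

    def column(self, name: str) -> np.ndarray:
        return self._columns[name]

    def design_for(self, target: str, structure: NetworkStructure | None = None):
        """(edges, X) for one equation: predictors of ``target`` plus an intercept."""
        structure = structure or self.structure
        edges = sorted(structure.predictors_of(target), key=Edge.key)
        cols = [self._columns[self.edge_column_name(e)] for e in edges]
        X = np.column_stack([np.ones(self.n_obs)] + cols) if cols else np.ones((self.n_obs, 1))
        return edges, X

    # -- estimation ------------------------------------------------------------------
    def fit(self, method: str = "auto") -> "EuSEMResults":
        """Estimate all free paths.  ``method``: "auto", "ols" (acyclic only), "fiml"."""
        acyclic = self.structure.is_acyclic()
        if method == "auto":
            method = "ols" if acyclic else "fiml"
        if method == "ols":
            if not acyclic:
                raise EstimationError("equation-wise estimation requires an acyclic A")
            return self._fit_ols()
        if method == "fiml":
            self._check_identification()
            return self._fit_fiml()
        raise ValueError(f"unknown method {method!r}")

    def _fit_ols(self) -> "EuSEMResults":
        rows = []
        resid = np.empty_like(self.endog)
        sigma2 = {}
        llf = 0.0
        n = self.n_obs
        for j, target in enumerate(self.roi_names):
            edges, X = self.design_for(target)
            y = self.endog[:, j]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            e = y - X @ beta
            resid[:, j] = e
            ssr = float(e @ e)
            k = X.shape[1]
            s2_mle = ssr / n
            sigma2[target] = s2_mle
            llf += -0.5 * n * (np.log(2 * np.pi * s2_mle) + 1.0)
            xtx_inv = np.linalg.pinv(X.T @ X)
            se = np.sqrt(np.maximum(np.diag(xtx_inv), 0) * ssr / max(n - k, 1))
            for m, e_dge in enumerate(edges, start=1):
                b = float(beta[m])
                s = float(se[m])
                z = b / s if s > 0 else np.inf * np.sign(b)
                rows.append(self._edge_row(e_dge, b, s, z))
        return EuSEMResults(self, self.structure, pd.DataFrame(rows), resid, sigma2, llf, True, "ols")

    def _edge_row(self, edge: Edge, b: float, s: float, z: float) -> dict:
        return {
            "kind": edge.kind,
            "source": edge.source,
            "target": edge.target,
            "input": edge.input,
            "level": edge.level,
            "beta": b,
            "se": s,
            "z": z,
            "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0,
        }

    def _check_identification(self) -> None:
        cycles = self.structure.contemporaneous_cycles()
        if not cycles:
            return
        cyclic_nodes = {v for comp in cycles for v in comp}
        system_predetermined = {
            self.edge_column_name(e)
            for e in self.structure.edges
            if e.kind != "contemporaneous"
        }
        for target in sorted(cyclic_nodes):
            preds = self.structure.predictors_of(target)
            endo = [e for e in preds if e.kind == "contemporaneous"]
            included = {self.edge_column_name(e) for e in preds if e.kind != "contemporaneous"}
            excluded = system_predetermined - included
            if len(excluded) < len(endo):
                cyc = next(c for c in cycles if target in c)
                raise IdentificationError(
                    f"equation for {target!r} in contemporaneous cycle {cyc} has "
                    f"{len(endo)} endogenous predictors but only {len(excluded)} "
                    "excluded predetermined instruments"
                )

    def _fit_fiml(self) -> "EuSEMResults":
        p = len(self.roi_names)
        n = self.n_obs
        targets = {r: j for j, r in enumerate(self.roi_names)}
        edges = sorted(self.structure.edges, key=Edge.key)
        # design tensor: per-edge predictor column and target index
        cols = np.column_stack([self._columns[self.edge_column_name(e)] for e in edges])
        tgt_idx = np.array([targets[e.target] for e in edges])
        contemp = np.array([e.kind == "contemporaneous" for e in edges])
        src_idx = np.array(
            [targets[e.source] if e.kind == "contemporaneous" else -1 for e in edges]
        )
        Y = self.endog

        def unpack(theta):
            betas = theta[: len(edges)]
            mu = theta[len(edges) : len(edges) + p]
            A = np.zeros((p, p))
            A[tgt_idx[contemp], src_idx[contemp]] = betas[contemp]
            return betas, mu, A

        def resid_of(theta):
            betas, mu, A = unpack(theta)
            pred = np.zeros_like(Y)
            for m in range(len(edges)):
                pred[:, tgt_idx[m]] += betas[m] * cols[:, m]
            return Y - pred - mu, A

        def negll(theta):
            e, A = resid_of(theta)
            sign, logdet = np.linalg.slogdet(np.eye(p) - A)
            if sign <= 0:
                return 1e12
            s2 = np.maximum(np.mean(e**2, axis=0), 1e-12)
            return -(n * logdet - 0.5 * n * np.sum(np.log(2 * np.pi * s2) + 1.0))

        # start from equation-wise values ignoring the Jacobian
        theta0 = np.zeros(len(edges) + p)
        for j, target in enumerate(self.roi_names):
            eqs, X = self.design_for(target)
            beta, *_ = np.linalg.lstsq(X, self.endog[:, j], rcond=None)
            theta0[j + len(edges)] = beta[0]
            for m, e_dge in enumerate(eqs, start=1):
                theta0[edges.index(e_dge)] = beta[m]
        res = optimize.minimize(negll, theta0, method="BFGS", options={"maxiter": 500})
        # BFGS may stop on precision loss with an essentially zero gradient; accept that
        converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3 * max(
            1.0, abs(float(res.fun))
        ) ** 0.5
        theta = res.x
        e, A = resid_of(theta)
        s2 = np.maximum(np.mean(e**2, axis=0), 1e-12)
        llf = -float(res.fun)
        # observed-information SEs via central-difference Hessian on the path block
        hess = _numeric_hessian(negll, theta)
        try:
            cov = np.linalg.inv(hess)
            se_all = np.sqrt(np.maximum(np.diag(cov), 0))
        except np.linalg.LinAlgError:
            se_all = np.full(len(theta), np.nan)
            converged = False
        rows = []
        for m, e_dge in enumerate(edges):
            b = float(theta[m])
            s = float(se_all[m])
            z = b / s if s and np.isfinite(s) and s > 0 else np.nan
            row = self._edge_row(e_dge, b, s, z if np.isfinite(z) else 0.0)
            if not np.isfinite(z):
                row["z"], row["p"] = np.nan, np.nan
            rows.append(row)
        sigma2 = {r: float(s2[j]) for j, r in enumerate(self.roi_names)}
        return EuSEMResults(
            self, self.structure, pd.DataFrame(rows), e, sigma2, llf, converged, "fiml"
        )


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


@dataclass
class EuSEMResults:
    """Fitted euSEM: per-path estimates, likelihood, fit indices, score tests."""

    model: EuSEM
    structure: NetworkStructure
    edge_table: pd.DataFrame
    resid: np.ndarray
    sigma2: dict
    llf: float
    converged: bool
    method: str

    # -- parameter access --------------------------------------------------------------
    def beta(self, edge: Edge) -> float:
        row = self._row(edge)
        return float(row["beta"])

    def zvalue(self, edge: Edge) -> float:
        return float(self._row(edge)["z"])

    def _row(self, edge: Edge) -> pd.Series:
        t = self.edge_table
        sel = t[
            (t["kind"] == edge.kind)
            & (t["source"] == edge.source)
            & (t["target"] == edge.target)
            & (t["input"].fillna("") == (edge.input or ""))
        ]
        if len(sel) != 1:
            raise KeyError(f"edge {edge.label()} not in fit")
        return sel.iloc[0]

    # -- fit indices --------------------------------------------------------------------
    @cached_property
    def fit_indices(self) -> dict:
        """RMSEA / SRMR / CFI / NNFI plus chi-squares, dfs, and the 2-of-4 verdict.

        Computed from the covariance structure over [lagged ROIs, convolved inputs,
        bilinear terms in the model, ROIs], with the exogenous block saturated and an
        independence baseline with free variances.
        """
        if not self.converged:
            raise NotConvergedError("fit indices requested from a non-converged fit")
        m = self.model
        exog_names = [f"lag:{r}" for r in m.roi_names]
        exog_names += [f"u:{k}" for k in m.input_names]
        exog_names += sorted(
            {m.edge_column_name(e) for e in self.structure.of_kind("bilinear")}
        )
        exog_cols = []
        kept_names = []
        for name in exog_names:
            c = m.column(name)
            if np.var(c) > 1e-12:
                exog_cols.append(c)
                kept_names.append(name)
        q = len(kept_names)
        p = len(m.roi_names)
        Z = np.column_stack(exog_cols + [m.endog[:, j] for j in range(p)])
        N = m.n_obs
        S = np.cov(Z, rowvar=False, ddof=0)
        # implied covariance from the reduced form
        A = np.zeros((p, p))
        C = np.zeros((p, q))
        ridx = {r: j for j, r in enumerate(m.roi_names)}
        cidx = {nm: j for j, nm in enumerate(kept_names)}
        for row in self.edge_table.itertuples(index=False):
            e = Edge(row.kind, row.source, row.target, row.input if row.input else None)
            if e.kind == "contemporaneous":
                A[ridx[e.target], ridx[e.source]] = row.beta
            else:
                nm = m.edge_column_name(e)
                if nm in cidx:
                    C[ridx[e.target], cidx[nm]] = row.beta
        inv_ia = np.linalg.inv(np.eye(p) - A)
        psi = np.diag([self.sigma2[r] for r in m.roi_names])
        s_xx = S[:q, :q]
        g = inv_ia @ C
        sig = np.empty_like(S)
        sig[:q, :q] = s_xx
        sig[q:, :q] = g @ s_xx
        sig[:q, q:] = sig[q:, :q].T
        sig[q:, q:] = inv_ia @ (C @ s_xx @ C.T + psi) @ inv_ia.T
        ptot = q + p
        sign_s, logdet_s = np.linalg.slogdet(S)
        sign_m, logdet_m = np.linalg.slogdet(sig)
        if sign_s <= 0 or sign_m <= 0:
            raise EstimationError("singular sample or implied covariance")
        f_ml = float(logdet_m - logdet_s + np.trace(S @ np.linalg.inv(sig)) - ptot)
        f_ml = max(f_ml, 0.0)
        n_free = q * (q + 1) // 2 + len(self.structure.edges) + p
        df = ptot * (ptot + 1) // 2 - n_free
        chisq = (N - 1) * f_ml
        # independence baseline with free variances
        f_base = float(np.sum(np.log(np.diag(S))) - logdet_s)
        chisq_b = (N - 1) * f_base
        df_b = ptot * (ptot + 1) // 2 - ptot
        rmsea = float(np.sqrt(max(chisq - df, 0) / (df * (N - 1)))) if df > 0 else 0.0
        d = np.sqrt(np.diag(S))
        std_resid = (S - sig) / np.outer(d, d)
        tri = np.tril_indices(ptot)
        srmr = float(np.sqrt(np.mean(std_resid[tri] ** 2)))
        num = max(chisq - df, 0.0)
        den = max(chisq_b - df_b, num, 1e-12)
        cfi = float(1.0 - num / den) if den > 0 else 1.0
        if df > 0 and df_b > 0 and chisq_b / df_b > 1:
            nnfi = float((chisq_b / df_b - chisq / df) / (chisq_b / df_b - 1.0))
        else:
            nnfi = 1.0
        out = {
            "rmsea": rmsea,
            "srmr": srmr,
            "cfi": cfi,
            "nnfi": nnfi,
            "chisq": float(chisq),
            "df": int(df),
            "chisq_baseline": float(chisq_b),
            "df_baseline": int(df_b),
        }
        out["excellent"] = excellent_fit_verdict(out)
        return out

    # -- score tests ---------------------------------------------------------------------
    @cached_property
    def _score_blocks(self) -> dict:
        """Shared pieces of the conditional-likelihood score test.

        The model seen through the conditional distribution y | x is
        N(Pi x, Omega) with reduced form Pi = B C and Omega = B Psi B',
        B = (I - A)^-1 and x the full predetermined column set (lags, convolved
        inputs, all bilinear products).  At the ML estimates the scores of every free
        parameter vanish; a candidate path's Lagrange-multiplier statistic is
        U^2 / (I_nn - I_no I_oo^-1 I_on) from the expected information, which is
        asymptotically chi-square(1).  Unlike an equation-wise regression score, this
        accounts for covariance already reproduced through other paths (e.g. the mirror
        of an included contemporaneous path gains ~nothing and scores ~0).
        """
        m = self.model
        p = len(m.roi_names)
        ridx = {r: j for j, r in enumerate(m.roi_names)}
        all_exog = [f"lag:{r}" for r in m.roi_names]
        all_exog += [f"u:{k}" for k in m.input_names]
        all_exog += [f"bl:{k}:{r}" for k in m.input_names for r in m.roi_names]
        kept = [nm for nm in all_exog if np.var(m.column(nm)) > 1e-12]
        cidx = {nm: j for j, nm in enumerate(kept)}
        X = np.column_stack([m.column(nm) for nm in kept])
        X = X - X.mean(axis=0)
        n = m.n_obs
        qx = len(kept)
        A = np.zeros((p, p))
        C = np.zeros((p, qx))
        psi = np.array([self.sigma2[r] for r in m.roi_names])
        params: list[tuple] = []
        for row in self.edge_table.itertuples(index=False):
            e = Edge(row.kind, row.source, row.target, row.input if row.input else None)
            if e.kind == "contemporaneous":
                A[ridx[e.target], ridx[e.source]] = row.beta
                params.append(("A", ridx[e.target], ridx[e.source]))
            else:
                nm = m.edge_column_name(e)
                if nm in cidx:
                    C[ridx[e.target], cidx[nm]] = row.beta
                    params.append(("C", ridx[e.target], cidx[nm]))
        params += [("P", j, j) for j in range(p)]
        B = np.linalg.inv(np.eye(p) - A)
        Pi = B @ C
        Omega = B @ np.diag(psi) @ B.T
        Oinv = np.linalg.inv(Omega)
        E = self.resid @ B.T  # reduced-form residuals
        R = E.T @ E / n
        Sxe = X.T @ E / n
        Sxx = X.T @ X / n
        W = Oinv - Oinv @ R @ Oinv

        def derivs(kind, r, s):
            """(dPi, dOmega) for one parameter."""
            b_r = B[:, r]
            if kind == "A":
                d_pi = np.outer(b_r, Pi[s, :])
                d_om = np.outer(b_r, Omega[s, :])
                d_om = d_om + d_om.T
            elif kind == "C":
                d_pi = np.zeros((p, qx))
                d_pi[:, s] = b_r
                d_om = None
            else:  # Psi diagonal
                d_pi = None
                d_om = np.outer(b_r, b_r)
            return d_pi, d_om

        def score_and_info(kind, r, s):
            d_pi, d_om = derivs(kind, r, s)
            u = 0.0
            if d_om is not None:
                u += -(n / 2.0) * float(np.sum(W * d_om))
            if d_pi is not None:
                u += n * float(np.sum((Oinv @ d_pi) * Sxe.T))
            q_mat = Oinv @ d_om @ Oinv if d_om is not None else None
            r_mat = Oinv @ d_pi @ Sxx if d_pi is not None else None
            return u, d_pi, d_om, q_mat, r_mat

        blocks = [score_and_info(*prm) for prm in params]
        n_free = len(params)
        i_oo = np.zeros((n_free, n_free))
        for a in range(n_free):
            _, dpi_a, dom_a, q_a, r_a = blocks[a]
            for b in range(a, n_free):
                _, dpi_b, dom_b, _, _ = blocks[b]
                v = 0.0
                if dom_a is not None and dom_b is not None:
                    v += (n / 2.0) * float(np.sum(q_a * dom_b))
                if dpi_a is not None and dpi_b is not None:
                    v += n * float(np.sum(r_a * dpi_b))
                i_oo[a, b] = i_oo[b, a] = v
        return {
            "ridx": ridx,
            "cidx": cidx,
            "n": n,
            "blocks": blocks,
            "i_oo": i_oo,
            "score_and_info": score_and_info,
        }

    def modification_indices(self, candidates: list[Edge], alpha: float = 0.05) -> pd.DataFrame:
        """Lagrange-multiplier (modification index) per absent candidate path.

        The 1-df score statistic measures how much the model fit would improve if the
        candidate were freed.  A candidate referencing a constant column (e.g. an
        all-zero input) gets MI = 0.
        """
        if not self.converged:
            raise NotConvergedError("modification indices from a non-converged fit")
        m = self.model
        for c in candidates:
            if self.structure.contains(c):
                raise StructureError(f"candidate {c.label()} already present in the model")
        sb = self._score_blocks
        ridx, cidx = sb["ridx"], sb["cidx"]
        blocks, i_oo = sb["blocks"], sb["i_oo"]
        score_and_info = sb["score_and_info"]
        n = sb["n"]
        try:
            i_oo_chol = np.linalg.cholesky(i_oo + 1e-10 * np.eye(len(i_oo)))
        except np.linalg.LinAlgError:
            i_oo_chol = None
        rows = []
        crit = stats.chi2.ppf(1 - alpha, df=1)
        for c in sorted(candidates, key=Edge.key):
            if c.kind == "contemporaneous":
                prm = ("A", ridx[c.target], ridx[c.source])
            else:
                nm = m.edge_column_name(c)
                if nm not in cidx:
                    rows.append(self._mi_row(c, 0.0, crit))
                    continue
                prm = ("C", ridx[c.target], cidx[nm])
            u, dpi_n, dom_n, q_n, r_n = score_and_info(*prm)
            i_nn = 0.0
            if dom_n is not None:
                i_nn += (n / 2.0) * float(np.sum(q_n * dom_n))
            if dpi_n is not None:
                i_nn += n * float(np.sum(r_n * dpi_n))
            i_no = np.zeros(len(blocks))
            for a, (_, dpi_a, dom_a, _, _) in enumerate(blocks):
                v = 0.0
                if dom_n is not None and dom_a is not None:
                    v += (n / 2.0) * float(np.sum(q_n * dom_a))
                if dpi_n is not None and dpi_a is not None:
                    v += n * float(np.sum(r_n * dpi_a))
                i_no[a] = v
            if i_oo_chol is not None:
                sol = np.linalg.solve(i_oo + 1e-10 * np.eye(len(i_oo)), i_no)
                denom = i_nn - float(i_no @ sol)
            else:
                denom = i_nn
            mi = 0.0 if denom <= 1e-9 else max(u * u / denom, 0.0)
            rows.append(self._mi_row(c, mi, crit))
        return pd.DataFrame(rows)

    @staticmethod
    def _mi_row(c: Edge, mi: float, crit: float) -> dict:
        return {
            "kind": c.kind,
            "source": c.source,
            "target": c.target,
            "input": c.input,
            "mi": float(mi),
            "p": float(stats.chi2.sf(mi, df=1)),
            "significant": bool(mi > crit),
        }

    def design_for_target(self, target: str):
        return self.model.design_for(target, self.structure)

    def prune_check(self, alpha: float = 0.05, levels=("group", "individual")) -> list[Edge]:
        """Non-AR paths whose two-sided Wald p >= alpha (candidates for pruning)."""
        if not self.converged:
            raise NotConvergedError("prune check on a non-converged fit")
        out = []
        for row in self.edge_table.itertuples(index=False):
            e = Edge(row.kind, row.source, row.target, row.input if row.input else None, row.level)
            if e.is_ar or e.level not in levels:
                continue
            if not np.isfinite(row.p) or row.p >= alpha:
                out.append(e)
        return sorted(out, key=Edge.key)

    # -- reporting ---------------------------------------------------------------------
    def summary(self) -> str:
        fi = self.fit_indices if self.converged else None
        lines = [
            "euSEM fit" + ("" if self.converged else " (NOT CONVERGED)"),
            f"  method: {self.method}   T(effective): {self.model.n_obs}   "
            f"log-likelihood: {self.llf:.2f}",
        ]
        if fi:
            lines.append(
                f"  chi2({fi['df']}) = {fi['chisq']:.2f}   RMSEA = {fi['rmsea']:.3f}   "
                f"SRMR = {fi['srmr']:.3f}   CFI = {fi['cfi']:.3f}   NNFI = {fi['nnfi']:.3f}"
                f"   excellent fit: {fi['excellent']}"
            )
        t = self.edge_table.copy()
        t["path"] = [
            Edge(r.kind, r.source, r.target, r.input if r.input else None).label()
            for r in t.itertuples(index=False)
        ]
        cols = ["path", "kind", "level", "beta", "se", "z", "p"]
        lines.append(t[cols].to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)
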