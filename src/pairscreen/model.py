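"""Hierarchical guide-efficacy / gene-effect / interaction model.

Each construct's expected LFC is built from three layers: a latent
efficacy x in [0, 1] per guide (how completely the guide knocks its gene
down), a single-knockdown fitness effect y per gene (log2 depletion at
the screen endpoint under full knockdown), and an interaction effect s
per unordered gene pair (deviation of the double knockdown from
additivity at full efficacy). For a construct carrying guides a and b:

* inter-gene (genes g != h):  mu = x_a y_g + x_b y_h + x_a x_b s_gh
* gene x NT control:          mu = x_a y_g
* intra-gene (same gene):     mu = (1 - (1 - x_a)(1 - x_b)) y_g
* NT x NT:                    mu = 0

Pair efficacy is the product x_a x_b; two guides on the same gene
combine as a probabilistic union. NT guides have x = 0 by definition.
Identifiability is fixed by anchoring each gene's strongest guide at
x = 1 (y is then the effect at full knockdown).

The fit minimizes the penalized least squares objective

    sum_{c,r} (LFC_cr - mu_c)^2 + ridge * (|y|^2 + |s|^2)

by block coordinate descent: exact linear solves for y and for s given
x, clamped coordinate updates for x in [0, 1], then the per-gene
anchor rescaling — each step is deterministic, so the fit is fully
reproducible.

Interaction scores follow the screen's reporting convention: with
scaling factor lambda, the sensitive deviation is
``T - lambda (y_g + y_h)`` and the strong deviation is
``T - min(y_g, y_h)`` where ``T = y_g + y_h + s`` is the model-implied
full-efficacy double-knockdown effect. Deviations are clipped at zero
from above, so every reported score is <= 0 and more negative means a
stronger synthetic-lethal interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import LibraryDesign

DEFAULT_RIDGE = 1e-3
DEFAULT_LAMBDA = 1.0
DEFAULT_SL_CUTOFF = -1.0


@dataclass
class ModelFit:
    """Point estimates of guide efficacies, gene effects and interactions."""

    x: pd.Series  # guide_id -> efficacy in [0, 1]
    y: pd.Series  # gene -> full-efficacy single-knockdown effect
    s: pd.Series  # (gene_a, gene_b) sorted -> interaction effect
    sigma: float
    converged: bool
    n_iter: int
    seed: int
    ridge: float = DEFAULT_RIDGE
    objective: float = float("nan")

    def s_lookup(self, gene_a: str, gene_b: str) -> float:
        key = tuple(sorted((gene_a, gene_b)))
        return float(self.s.loc[key])

    def to_dict(self) -> dict:
        return {
            "x": self.x.to_dict(),
            "y": self.y.to_dict(),
            "s": [
                {"gene_a": a, "gene_b": b, "s": float(v)}
                for (a, b), v in self.s.items()
            ],
            "sigma": self.sigma,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "ridge": self.ridge,
            "objective": self.objective,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        s = pd.Series(
            {(r["gene_a"], r["gene_b"]): r["s"] for r in d["s"]}, dtype=float
        )
        if len(s):
            s.index = pd.MultiIndex.from_tuples(s.index)
        return cls(
            x=pd.Series(d["x"], dtype=float),
            y=pd.Series(d["y"], dtype=float),
            s=s,
            sigma=d["sigma"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            seed=d["seed"],
            ridge=d.get("ridge", DEFAULT_RIDGE),
            objective=d.get("objective", float("nan")),
        )


@dataclass(frozen=True)
class ScoreParams:
    """Scoring convention knobs: lambda scaling and synthetic-lethal cutoff."""

    lambda_: float = DEFAULT_LAMBDA
    sl_cutoff: float = DEFAULT_SL_CUTOFF

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be non-negative")


class _Problem:
    """Element-wise arrays extracted from (lfc, design) for the solver."""

    # element type codes
    INTER, INTRA, TNT, NTNT = 0, 1, 2, 3

    def __init__(self, lfc: pd.DataFrame, design: LibraryDesign):
        if not np.isfinite(lfc.values).all():
            raise ValueError("LFC table contains non-finite values")
        elements = [e for e in design.elements if e.element_id in set(lfc.index)]
        if not elements:
            raise ValueError("no library elements present in LFC table")

        guides = design.guides
        t_guides = sorted(
            {
                gid
                for e in elements
                for gid in (e.guide_a, e.guide_b)
                if guides[gid].is_targeting
            }
        )
        genes = sorted(
            {g for e in elements for g in (e.gene_a, e.gene_b) if g != "NT"}
        )
        self.guide_ids = t_guides
        self.genes = genes
        gi = {g: k for k, g in enumerate(t_guides)}
        ge = {g: k for k, g in enumerate(genes)}

        pairs = sorted(
            {
                tuple(sorted((e.gene_a, e.gene_b)))
                for e in elements
                if e.pair_class == "inter_gene"
            }
        )
        self.pairs = pairs
        pi = {p: k for k, p in enumerate(pairs)}

        n = len(elements)
        self.etype = np.empty(n, dtype=np.int64)
        self.ia = np.full(n, -1, dtype=np.int64)
        self.ib = np.full(n, -1, dtype=np.int64)
        self.ga = np.full(n, -1, dtype=np.int64)
        self.gb = np.full(n, -1, dtype=np.int64)
        self.pidx = np.full(n, -1, dtype=np.int64)
        code = {
            "inter_gene": self.INTER,
            "intra_gene": self.INTRA,
            "targeting_nt": self.TNT,
            "nt_nt": self.NTNT,
        }
        for k, e in enumerate(elements):
            self.etype[k] = code[e.pair_class]
            if guides[e.guide_a].is_targeting:
                self.ia[k] = gi[e.guide_a]
                self.ga[k] = ge[e.gene_a]
            if guides[e.guide_b].is_targeting:
                self.ib[k] = gi[e.guide_b]
                self.gb[k] = ge[e.gene_b]
            if e.pair_class == "inter_gene":
                self.pidx[k] = pi[tuple(sorted((e.gene_a, e.gene_b)))]

        sub = lfc.loc[[e.element_id for e in elements]]
        self.obs = sub.values  # n x n_replicates
        self.lbar = self.obs.mean(axis=1)
        self.w = np.full(n, float(sub.shape[1]))
        self.element_ids = [e.element_id for e in elements]

        # every modeled gene must have NT-anchored data
        nt_genes = {
            (e.gene_a if e.gene_b == "NT" else e.gene_b)
            for e in elements
            if e.pair_class == "targeting_nt"
        }
        orphans = [g for g in genes if g not in nt_genes]
        if orphans:
            raise ValueError(
                f"genes without NT-paired measurements: {orphans}"
            )

        self.mismatch = np.array(
            [guides[g].guide_type == "mismatch" for g in t_guides]
        )

        # per-guide element lists for the coordinate updates on x
        self.by_guide: list[dict[str, np.ndarray]] = []
        for j in range(len(t_guides)):
            on_a = np.where(self.ia == j)[0]
            on_b = np.where(self.ib == j)[0]
            idx = np.concatenate([on_a, on_b])
            partner_guide = np.concatenate([self.ib[on_a], self.ia[on_b]])
            partner_gene = np.concatenate([self.gb[on_a], self.ga[on_b]])
            own_gene = np.concatenate([self.ga[on_a], self.gb[on_b]])
            self.by_guide.append(
                {
                    "idx": idx,
                    "etype": self.etype[idx],
                    "partner_guide": partner_guide,
                    "partner_gene": partner_gene,
                    "own_gene": own_gene,
                    "pidx": self.pidx[idx],
                    "w": self.w[idx],
                    "lbar": self.lbar[idx],
                }
            )

    # --- model prediction -------------------------------------------------
    def mu(self, x: np.ndarray, y: np.ndarray, s: np.ndarray) -> np.ndarray:
        xa = np.where(self.ia >= 0, x[np.maximum(self.ia, 0)], 0.0)
        xb = np.where(self.ib >= 0, x[np.maximum(self.ib, 0)], 0.0)
        ya = np.where(self.ga >= 0, y[np.maximum(self.ga, 0)], 0.0)
        yb = np.where(self.gb >= 0, y[np.maximum(self.gb, 0)], 0.0)
        mu = xa * ya + xb * yb
        inter = self.etype == self.INTER
        if inter.any():
            mu[inter] += (xa * xb)[inter] * s[np.maximum(self.pidx, 0)][inter]
        intra = self.etype == self.INTRA
        mu[intra] -= (xa * xb * ya)[intra]  # union, not sum, of same-gene efficacy
        return mu

    def objective(self, x, y, s, ridge) -> float:
        mu = self.mu(x, y, s)
        sse = float((self.w * (self.lbar - mu) ** 2).sum())
        # replicate scatter around the per-element mean is constant in the
        # parameters; include it so the value matches the full objective
        sse += float(((self.obs - self.lbar[:, None]) ** 2).sum())
        return sse + ridge * (float(y @ y) + float(s @ s))


def fit_interaction_model(
    lfc: pd.DataFrame,
    design: LibraryDesign,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
    ridge: float = DEFAULT_RIDGE,
) -> ModelFit:
    """Fit guide efficacies, gene effects and pair interactions to LFCs.

    Deterministic given its inputs; ``seed`` is recorded in the fit (it
    would only matter if stochastic restarts were added) so results are
    traceable.
    """
    prob = _Problem(lfc, design)
    G, P, J = len(prob.genes), len(prob.pairs), len(prob.guide_ids)

    x = np.where(prob.mismatch, 0.5, 1.0).astype(float)
    s = np.zeros(P)
    # y init: mean NT-partner LFC per gene
    y = np.zeros(G)
    tnt = prob.etype == prob.TNT
    own = np.where(prob.ga >= 0, prob.ga, prob.gb)
    num = np.bincount(own[tnt], weights=prob.lbar[tnt], minlength=G)
    den = np.bincount(own[tnt], minlength=G)
    y = num / np.maximum(den, 1)

    gene_of_guide = np.full(J, -1, dtype=np.int64)
    for bg, j in zip(prob.by_guide, range(J)):
        if len(bg["own_gene"]):
            gene_of_guide[j] = bg["own_gene"][0]
    pair_ga = np.array([prob.genes.index(a) for a, _ in prob.pairs], dtype=np.int64) if P else np.empty(0, np.int64)
    pair_gb = np.array([prob.genes.index(b) for _, b in prob.pairs], dtype=np.int64) if P else np.empty(0, np.int64)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x_old, y_old, s_old = x.copy(), y.copy(), s.copy()

        xa = np.where(prob.ia >= 0, x[np.maximum(prob.ia, 0)], 0.0)
        xb = np.where(prob.ib >= 0, x[np.maximum(prob.ib, 0)], 0.0)
        inter = prob.etype == prob.INTER
        intra = prob.etype == prob.INTRA

        # ---- y block: exact ridge solve given x and s
        coef_a = xa.copy()
        coef_b = xb.copy()
        # intra elements involve a single gene with union efficacy
        coef_a[intra] = xa[intra] + xb[intra] - xa[intra] * xb[intra]
        coef_b[intra] = 0.0
        const = np.zeros(len(xa))
        if P:
            const[inter] = (xa * xb)[inter] * s[np.maximum(prob.pidx, 0)][inter]
        r = prob.lbar - const
        M = np.zeros((G, G))
        b = np.zeros(G)
        mask_a = prob.ga >= 0
        mask_b = (prob.gb >= 0) & ~intra
        np.add.at(M, (prob.ga[mask_a], prob.ga[mask_a]), (prob.w * coef_a**2)[mask_a])
        np.add.at(b, prob.ga[mask_a], (prob.w * coef_a * r)[mask_a])
        np.add.at(M, (prob.gb[mask_b], prob.gb[mask_b]), (prob.w * coef_b**2)[mask_b])
        np.add.at(b, prob.gb[mask_b], (prob.w * coef_b * r)[mask_b])
        both = mask_a & mask_b
        cross = (prob.w * coef_a * coef_b)[both]
        np.add.at(M, (prob.ga[both], prob.gb[both]), cross)
        np.add.at(M, (prob.gb[both], prob.ga[both]), cross)
        y = np.linalg.solve(M + ridge * np.eye(G), b)

        # ---- s block: independent ridge updates given x and y
        if P:
            ya = np.where(prob.ga >= 0, y[np.maximum(prob.ga, 0)], 0.0)
            yb = np.where(prob.gb >= 0, y[np.maximum(prob.gb, 0)], 0.0)
            coef = (xa * xb)[inter]
            resid = (prob.lbar - xa * ya - xb * yb)[inter]
            wi = prob.w[inter]
            p = prob.pidx[inter]
            num = np.bincount(p, weights=wi * coef * resid, minlength=P)
            den = np.bincount(p, weights=wi * coef**2, minlength=P) + ridge
            s = num / den

        # ---- x sweep: clamped Gauss-Seidel coordinate updates
        for j in range(J):
            bg = prob.by_guide[j]
            if not len(bg["idx"]):
                continue
            pg = bg["partner_guide"]
            xp = np.where(pg >= 0, x[np.maximum(pg, 0)], 0.0)
            g_own = bg["own_gene"]
            y_own = y[g_own]
            et = bg["etype"]
            coef = np.where(et == prob.TNT, y_own, 0.0)
            offset = np.zeros(len(xp))
            m_intra = et == prob.INTRA
            coef[m_intra] = (y_own * (1.0 - xp))[m_intra]
            offset[m_intra] = (xp * y_own)[m_intra]
            m_inter = et == prob.INTER
            sp = s[np.maximum(bg["pidx"], 0)] if P else np.zeros(len(xp))
            y_partner = np.where(
                bg["partner_gene"] >= 0, y[np.maximum(bg["partner_gene"], 0)], 0.0
            )
            coef[m_inter] = (y_own + xp * sp)[m_inter]
            offset[m_inter] = (xp * y_partner)[m_inter]
            den_j = float((bg["w"] * coef**2).sum())
            if den_j < 1e-12:
                continue
            num_j = float((bg["w"] * coef * (bg["lbar"] - offset)).sum())
            x[j] = min(1.0, max(0.0, num_j / den_j))

        # ---- per-gene anchor: strongest guide pinned at efficacy 1
        m = np.zeros(G)
        np.maximum.at(m, gene_of_guide[gene_of_guide >= 0], x[gene_of_guide >= 0])
        scale = np.where(m > 0, m, 1.0)
        x = x / scale[gene_of_guide]
        y = y * scale
        if P:
            s = s * scale[pair_ga] * scale[pair_gb]

        delta = max(
            np.abs(x - x_old).max(initial=0.0),
            np.abs(y - y_old).max(initial=0.0),
            np.abs(s - s_old).max(initial=0.0),
        )
        if delta < tol:
            converged = True
            break

    mu = prob.mu(x, y, s)
    resid = prob.obs - mu[:, None]
    sigma = float(np.sqrt(np.mean(resid**2))) if resid.size else 0.0
    return ModelFit(
        x=pd.Series(x, index=prob.guide_ids, name="efficacy"),
        y=pd.Series(y, index=prob.genes, name="gene_effect"),
        s=pd.Series(
            s,
            index=pd.MultiIndex.from_tuples(prob.pairs, names=["gene_a", "gene_b"])
            if P
            else pd.MultiIndex.from_arrays([[], []], names=["gene_a", "gene_b"]),
            name="interaction",
        ),
        sigma=max(sigma, 1e-12),
        converged=converged,
        n_iter=it,
        seed=seed,
        ridge=ridge,
        objective=prob.objective(x, y, s, ridge),
    )


def score_gene_pairs(fit: ModelFit, params: ScoreParams = ScoreParams()) -> pd.DataFrame:
    """Sensitive and strong interaction scores per gene pair.

    Positive deviations (double knockdown *less* depleted than expected)
    are clipped to 0; the reported scores are therefore <= 0, with the
    synthetic-lethal flag set where sensitive_score <= sl_cutoff.
    """
    if not fit.converged:
        warnings.warn("scoring a non-converged model fit", stacklevel=2)
    rows = []
    for (ga, gb), s in fit.s.items():
        yg = float(fit.y.loc[ga])
        yh = float(fit.y.loc[gb])
        total = yg + yh + s
        d_sens = total - params.lambda_ * (yg + yh)
        d_strong = total - min(yg, yh)
        sens = min(d_sens, 0.0)
        strong = min(d_strong, 0.0)
        a, b = sorted((ga, gb))
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "raw_sensitive": d_sens,
                "raw_strong": d_strong,
                "sensitive_score": sens,
                "strong_score": strong,
                "is_synthetic_lethal": sens <= params.sl_cutoff,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "raw_sensitive", "raw_strong",
            "sensitive_score", "strong_score", "is_synthetic_lethal",
        ],
    )
    return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def predict_lfc(
    fit: ModelFit,
    design: LibraryDesign,
    lfc: pd.DataFrame | None = None,
) -> tuple[pd.Series, dict]:
    """Model-implied LFC per library element, plus a residual summary.

    Elements involving guides or genes absent from the fit (for example
    dropped by the mismatch substitution) predict NaN.
    """
    x = fit.x
    y = fit.y
    preds = {}
    for e in design.elements:
        if e.pair_class == "nt_nt":
            preds[e.element_id] = 0.0
            continue
        try:
            if e.pair_class == "targeting_nt":
                gid, gene = (
                    (e.guide_a, e.gene_a) if e.gene_b == "NT" else (e.guide_b, e.gene_b)
                )
                preds[e.element_id] = float(x.loc[gid] * y.loc[gene])
            elif e.pair_class == "intra_gene":
                xa, xb = float(x.loc[e.guide_a]), float(x.loc[e.guide_b])
                preds[e.element_id] = (1 - (1 - xa) * (1 - xb)) * float(y.loc[e.gene_a])
            else:
                xa, xb = float(x.loc[e.guide_a]), float(x.loc[e.guide_b])
                preds[e.element_id] = (
                    xa * float(y.loc[e.gene_a])
                    + xb * float(y.loc[e.gene_b])
                    + xa * xb * fit.s_lookup(e.gene_a, e.gene_b)
                )
        except KeyError:
            preds[e.element_id] = float("nan")
    pred = pd.Series(preds, name="predicted_lfc")
    summary: dict = {"n_elements": len(pred), "n_predicted": int(pred.notna().sum())}
    if lfc is not None:
        common = [i for i in lfc.index if i in pred.index and np.isfinite(pred[i])]
        if common:
            resid = lfc.loc[common].values - pred.loc[common].values[:, None]
            summary["rmse"] = float(np.sqrt(np.mean(resid**2)))
    return pred, summary
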