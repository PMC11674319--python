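"""Between-group inference on aligned gradients.

Per parcel, the three aligned gradient values of each subject form a
trivariate response Y, modelled as

    Y = intercept + group + age + sex + site

by multivariate least squares. The group effect is tested jointly across
the three gradients with Hotelling's T^2 (the multivariate generalization
of the squared t statistic), transformed to an exact F statistic, with
Benjamini-Hochberg FDR correction across parcels.

Spatial correlations between parcel maps are tested against a spin
permutation null: parcel centroids are randomly rotated on the sphere
(mirror-conjugate rotations for the two hemispheres) and values
reassigned, preserving the spatial autocorrelation that would otherwise
inflate parametric p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .parcellation import ParcellationScheme


@dataclass
class EffectMap:
    """Per-parcel group-difference statistics."""

    t2: np.ndarray
    f: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    df: tuple[int, int]  # (q, nu - q + 1) of the F reference distribution
    alpha: float = 0.05

    @property
    def n_parcels(self) -> int:
        return len(self.t2)

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": np.arange(self.n_parcels),
                "T2": self.t2,
                "F": self.f,
                "p": self.p,
                "q": self.q,
                "significant": self.significant.astype(int),
            }
        )


@dataclass
class SpinNull:
    """Observed map correlation against its spin-permutation null."""

    observed_r: float
    null_r: np.ndarray
    p: float
    n_perm: int


def build_design(
    covariates: pd.DataFrame,
    include_motion: bool = False,
    drop_site: str | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, group (case=1), age, sex (M=1), site dummies.

    Site is one-hot encoded with one reference level dropped (the first in
    sorted order unless ``drop_site`` names another); with a single site no
    site columns are added. Group labels must be 'case'/'control'.
    """
    required = {"group", "age", "sex", "site"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariates missing columns: {sorted(missing)}")
    bad_groups = set(covariates["group"]) - {"case", "control"}
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")

    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    cols.append((covariates["group"] == "case").to_numpy(float))
    names.append("group")
    cols.append(covariates["age"].to_numpy(float))
    names.append("age")
    cols.append((covariates["sex"] == "M").to_numpy(float))
    names.append("sex")
    sites = sorted(set(covariates["site"]))
    if len(sites) > 1:
        ref = drop_site if drop_site is not None else sites[0]
        if ref not in sites:
            raise ValueError(f"drop_site {ref!r} not among sites {sites}")
        for s in sites:
            if s == ref:
                continue
            cols.append((covariates["site"] == s).to_numpy(float))
            names.append(f"site[{s}]")
    if include_motion:
        cols.append(covariates["motion"].to_numpy(float))
        names.append("motion")
    return np.column_stack(cols), names


def hotelling_t2(
    y: np.ndarray, x: np.ndarray, contrast: np.ndarray
) -> tuple[float, float, float, tuple[int, int]]:
    """Hotelling's T^2 for one contrast in a multivariate linear model.

    y is (n, q); x is (n, k) full rank; the contrast c selects a single
    coefficient row. With B the least-squares coefficients, E the
    residuals, nu = n - rank(X) and Sigma = E'E / nu,

        T^2 = (c'B) Sigma^-1 (c'B)' / (c' (X'X)^-1 c)
        F = T^2 (nu - q + 1) / (nu q)  ~  F(q, nu - q + 1).

    Returns (T^2, F, p, (df1, df2)).
    """
    n, q = y.shape
    xtx = x.T @ x
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    nu = n - rank
    if nu < q:
        raise ValueError(f"residual dof {nu} < response dimension {q}")
    xtx_inv = np.linalg.inv(xtx)
    b = xtx_inv @ x.T @ y
    e = y - x @ b
    sigma = e.T @ e / nu
    cb = contrast @ b  # (q,)
    denom = float(contrast @ xtx_inv @ contrast)
    try:
        sol = np.linalg.solve(sigma, cb)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular residual covariance (degenerate response)") from exc
    t2 = float(cb @ sol) / denom
    f = t2 * (nu - q + 1) / (nu * q)
    p = float(sps.f.sf(f, q, nu - q + 1))
    return t2, f, p, (q, nu - q + 1)


def fit_mglm(
    aligned: np.ndarray,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    include_motion: bool = False,
    drop_site: str | None = None,
) -> EffectMap:
    """Parcel-wise multivariate GLM with a Hotelling's T^2 group test.

    ``aligned`` is (subjects, parcels, q) with q the number of gradients
    (3 in the standard analysis). Each group must have at least two
    subjects. p-values are BH-adjusted across parcels.
    """
    aligned = np.asarray(aligned, dtype=float)
    if aligned.ndim != 3:
        raise ValueError(f"aligned must be (subjects, parcels, k), got {aligned.shape}")
    n, n_parcels, q = aligned.shape
    if len(covariates) != n:
        raise ValueError(
            f"{n} subjects in aligned but {len(covariates)} covariate rows"
        )
    counts = covariates["group"].value_counts()
    if counts.get("case", 0) < 2 or counts.get("control", 0) < 2:
        raise ValueError("need at least 2 subjects per group")
    x, names = build_design(
        covariates, include_motion=include_motion, drop_site=drop_site
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the aliased columns for the error message
        _, r = np.linalg.qr(x)
        aliased = [names[j] for j in range(x.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"design matrix rank deficient; aliased columns: {aliased}")
    contrast = np.zeros(x.shape[1])
    contrast[names.index("group")] = 1.0

    t2 = np.empty(n_parcels)
    f = np.empty(n_parcels)
    p = np.empty(n_parcels)
    df = (q, n - x.shape[1] - q + 1)
    for j in range(n_parcels):
        t2[j], f[j], p[j], df = hotelling_t2(aligned[:, j, :], x, contrast)
    qvals, significant = fdr_bh(p, alpha=alpha)
    return EffectMap(t2=t2, f=f, p=p, q=qvals, significant=significant, df=df,
                     alpha=alpha)


def fdr_bh(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation: orthonormalized Gaussian, det corrected to +1."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def spin_permutations(
    scheme: ParcellationScheme,
    n_perm: int,
    seed: int | None = None,
    method: str = "hungarian",
    rotations: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Spatial-null permutations of parcel indices via sphere rotations.

    Each permutation draws one uniform random rotation R, applies it to
    the left-hemisphere centroids and its mirror conjugate M R M (mirror
    about the sagittal plane) to the right, and reassigns parcels within
    each hemisphere. With ``method='hungarian'`` the reassignment is the
    optimal one-to-one matching between rotated and original centroids,
    so each null map is an exact permutation of the original (value
    multisets preserved per hemisphere). ``method='nearest'`` takes each
    parcel's value from its nearest source parcel under the rotation,
    which may duplicate values.

    Returns an (n_perm, p) integer array: row k maps parcel i to source
    parcel perm[k, i]. ``rotations`` may supply explicit left-hemisphere
    rotation matrices (one per permutation) instead of random draws —
    useful for diagnostics such as forcing the identity rotation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if method not in ("hungarian", "nearest"):
        raise ValueError(f"unknown spin method {method!r}")
    if rotations is not None and len(rotations) != n_perm:
        raise ValueError("need one rotation per permutation")
    rng = np.random.default_rng(seed)
    mirror = np.diag([-1.0, 1.0, 1.0])
    hemi_idx = {h: scheme.hemisphere_indices(h) for h in ("L", "R")}
    perms = np.empty((n_perm, scheme.n_parcels), dtype=int)
    for k in range(n_perm):
        rot_l = _random_rotation(rng) if rotations is None else rotations[k]
        rot = {"L": rot_l, "R": mirror @ rot_l @ mirror}
        for h in ("L", "R"):
            idx = hemi_idx[h]
            pts = scheme.centroids[idx]
            rotated = pts @ rot[h].T
            if method == "hungarian":
                # maximize total cosine alignment == minimize distance
                _, cols = linear_sum_assignment(-(rotated @ pts.T))
                perms[k, idx] = idx[cols]
            else:
                _, nearest = cKDTree(pts).query(rotated)
                perms[k, idx] = idx[nearest]
    return perms


def spin_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    scheme: ParcellationScheme,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "hungarian",
) -> SpinNull:
    """Spin permutation test of the correlation between two parcel maps.

    map_a is spatially permuted by random sphere rotations; the two-sided
    p-value uses the add-one estimator
    p = (1 + #{|null_r| >= |observed_r|}) / (n_perm + 1).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != (scheme.n_parcels,) or b.shape != (scheme.n_parcels,):
        raise ValueError("maps must be 1-D with one value per parcel")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant map: correlation undefined")
    observed = float(np.corrcoef(a, b)[0, 1])
    perms = spin_permutations(scheme, n_perm, seed=seed, method=method)
    permuted = a[perms]  # (n_perm, p)
    pc = permuted - permuted.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.sqrt((pc**2).sum(axis=1) * (bc**2).sum())
    null_r = (pc @ bc) / denom
    p = (1.0 + np.sum(np.abs(null_r) >= abs(observed))) / (n_perm + 1.0)
    return SpinNull(observed_r=observed, null_r=null_r, p=p, n_perm=n_perm)


def stratify_effects(
    effects: EffectMap, scheme: ParcellationScheme, by: str = "community"
) -> pd.DataFrame:
    """Per-community or per-hierarchy summary of the effect map."""
    if by not in ("community", "hierarchy"):
        raise ValueError(f"'by' must be 'community' or 'hierarchy', got {by!r}")
    labels = getattr(scheme, by)
    if effects.n_parcels != scheme.n_parcels:
        raise ValueError("effect map and scheme have different parcel counts")
    if any(lbl is None or (isinstance(lbl, float) and np.isnan(lbl)) for lbl in labels):
        raise ValueError("unlabeled parcels present")
    df = pd.DataFrame(
        {
            "label": labels,
            "T2": effects.t2,
            "significant": effects.significant.astype(int),
        }
    )
    out = (
        df.groupby("label", sort=True)
        .agg(
            mean_T2=("T2", "mean"),
            sd_T2=("T2", lambda v: float(np.std(v, ddof=0))),
            n_parcels=("T2", "size"),
            n_significant=("significant", "sum"),
        )
        .reset_index()
    )
    return out


def summarize_template(effects: EffectMap) -> dict:
    """Whole-map summary: mean and SD of T^2 plus significant-parcel count."""
    if effects.n_parcels == 0:
        raise ValueError("empty effect map")
    return {
        "mean_T2": float(np.mean(effects.t2)),
        "sd_T2": float(np.std(effects.t2, ddof=0)),
        "n_significant": effects.n_significant,
    }


def evaluate_template_utility(
    features: np.ndarray,
    covariates: pd.DataFrame,
    target: np.ndarray,
    task: str = "classify",
    n_folds: int = 5,
    n_repeats: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cross-validated template utility: classification or prediction.

    Features are the concatenated aligned gradients (G1 + G2 + G3, i.e.
    3p columns at p parcels) augmented with the encoded covariates.
    Classification uses a linear maximum-margin classifier (SVM),
    prediction an L2-penalized (ridge) linear regression, both inside a
    standardization pipeline. Folds are stratified for classification and
    drawn afresh per repeat from the repeat-specific seed. Returns one row
    per repeat (accuracy, or Pearson r and MAE) plus a trailing summary
    row with the mean and SD across repeats.
    """
    from sklearn.linear_model import Ridge
    from sklearn.metrics import accuracy_score, mean_absolute_error
    from sklearn.model_selection import KFold, StratifiedKFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    features = np.asarray(features, dtype=float)
    target = np.asarray(target)
    if task not in ("classify", "predict"):
        raise ValueError(f"task must be 'classify' or 'predict', got {task!r}")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    if len(features) != len(target) or len(features) != len(covariates):
        raise ValueError("features, target and covariates must have equal length")
    if len(features) < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} subjects")
    if task == "classify" and len(np.unique(target)) < 2:
        raise ValueError("classification target has a single class")

    x_cov, cov_names = build_design(covariates)
    keep = [j for j, name in enumerate(cov_names)
            if name not in ("intercept", "group")]
    x = np.hstack([features, x_cov[:, keep]])
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        rep_seed = int(rng.integers(2**31 - 1))
        if task == "classify":
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                       random_state=rep_seed)
            model = make_pipeline(
                StandardScaler(), LinearSVC(C=1.0, random_state=rep_seed)
            )
            pred = np.empty(len(target), dtype=target.dtype)
            for tr, te in splitter.split(x, target):
                model.fit(x[tr], target[tr])
                pred[te] = model.predict(x[te])
            rows.append({"repeat": rep, "accuracy": accuracy_score(target, pred)})
        else:
            splitter = KFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
            model = make_pipeline(StandardScaler(), Ridge(alpha=1.0))
            pred = np.empty(len(target), dtype=float)
            y = target.astype(float)
            for tr, te in splitter.split(x):
                model.fit(x[tr], y[tr])
                pred[te] = model.predict(x[te])
            r = float(np.corrcoef(pred, y)[0, 1]) if np.std(pred) > 0 else 0.0
            rows.append(
                {"repeat": rep, "r": r, "mae": mean_absolute_error(y, pred)}
            )
    df = pd.DataFrame(rows)
    metrics = [c for c in df.columns if c != "repeat"]
    summary = {"repeat": "mean±sd"}
    for m in metrics:
        summary[m] = float(df[m].mean())
        summary[f"{m}_sd"] = float(df[m].std(ddof=0))
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
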