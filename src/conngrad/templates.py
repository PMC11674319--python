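"""Group-level gradient templates and Procrustes alignment.

Individual gradient sets are only comparable across subjects after
rotation onto a common group-level template. Six template construction
strategies are supported:

1. cases + controls of the study cohort,
2. controls of the study cohort only,
3. cases of the study cohort only,
4. an independent reference cohort (e.g., a large high-quality normative
   dataset),
5. the strategy-1 template rotated onto the strategy-4 template,
6. the strategy-2 template rotated onto the strategy-4 template.

Sex-specific variants of the reference template are parameterizations of
strategies 4 and 5 with a filtered reference cohort, not separate code
paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.linalg import svd

from .connectome import (
    ConnectivityMatrix,
    distance_consensus_group_sc,
    fisher_z,
    group_average_fc,
    log_transform_sc,
)
from .embedding import GradientParams, GradientSet, embed_functional, embed_structural
from .parcellation import ParcellationScheme

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import SubjectRecord

logger = logging.getLogger(__name__)

STRATEGY_SELECTION = {
    1: "cases+controls",
    2: "controls_only",
    3: "cases_only",
    4: "reference",
    5: "cases+controls->reference",
    6: "controls_only->reference",
}


@dataclass(frozen=True)
class TemplateSpec:
    """One of the six template construction strategies."""

    strategy: int

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGY_SELECTION:
            raise ValueError(f"strategy must be in 1..6, got {self.strategy}")

    @property
    def uses_reference(self) -> bool:
        return self.strategy in (4, 5, 6)

    @property
    def description(self) -> str:
        return STRATEGY_SELECTION[self.strategy]


@dataclass
class RotationMatrix:
    """A k x k orthogonal matrix (rotation, possibly with reflection)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        r = self.matrix
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError(f"rotation must be square, got {r.shape}")
        if not np.allclose(r.T @ r, np.eye(r.shape[0]), atol=1e-8):
            raise ValueError("matrix is not orthogonal")


def procrustes_rotate(
    source: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, RotationMatrix]:
    """Orthogonal Procrustes: rotate ``source`` onto ``target``.

    Solves min_R ||source @ R - target||_F over the full orthogonal group
    (reflections allowed) via the SVD of source.T @ target. No centering
    and no scaling is applied: gradient magnitudes are compared across
    groups downstream, so the transform must be norm-preserving.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape:
        raise ValueError(f"shape mismatch: source {src.shape}, target {tgt.shape}")
    if src.ndim != 2 or src.shape[0] < src.shape[1]:
        raise ValueError(f"need a tall parcels-by-k matrix, got {src.shape}")
    m = src.T @ tgt
    u, s, vt = svd(m)
    if np.any(s < 1e-12 * max(s[0], 1e-300)):
        logger.warning("rank-deficient cross-product: Procrustes solution non-unique")
    r = u @ vt
    return src @ r, RotationMatrix(r)


def align_gradient_set(g: GradientSet, template: GradientSet) -> GradientSet:
    """Rotate one subject's gradients onto the template."""
    aligned, _ = procrustes_rotate(g.components, template.components)
    return g.copy_with(aligned)


def align_cohort(
    subjects: Sequence[GradientSet], template: GradientSet
) -> list[GradientSet]:
    """Independently rotate each subject's gradients onto the template."""
    out = []
    for i, g in enumerate(subjects):
        if g.components.shape != template.components.shape:
            raise ValueError(
                f"subject {i}: gradient shape {g.components.shape} does not "
                f"match template {template.components.shape}"
            )
        out.append(align_gradient_set(g, template))
    return out


def template_similarity(a: GradientSet, b: GradientSet) -> np.ndarray:
    """Pearson spatial correlation per gradient column."""
    x, y = a.components, b.components
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        if np.std(x[:, j]) == 0 or np.std(y[:, j]) == 0:
            raise ValueError(f"gradient column {j} is constant: correlation undefined")
        out[j] = np.corrcoef(x[:, j], y[:, j])[0, 1]
    return out


def group_connectivity(
    subjects: Sequence["SubjectRecord"],
    modality: str,
    scheme: ParcellationScheme | None = None,
    n_bins: int = 10,
) -> ConnectivityMatrix:
    """Group-representative connectivity matrix for one modality.

    FC: mean of subject-level Fisher-z matrices. SC: distance-dependent
    consensus on raw streamline counts, then log transform (consensus
    first, so edge frequencies are judged on the raw counts).
    """
    if not subjects:
        raise ValueError("empty subject selection")
    if modality == "functional":
        return group_average_fc([fisher_z(s.fc) for s in subjects])
    if modality == "structural":
        if scheme is None:
            raise ValueError("structural group matrix needs a parcellation scheme")
        return log_transform_sc(
            distance_consensus_group_sc([s.sc for s in subjects], scheme, n_bins)
        )
    raise ValueError(f"unknown modality {modality!r}")


def _embed_group(
    group_cm: ConnectivityMatrix,
    modality: str,
    scheme: ParcellationScheme | None,
    params: GradientParams,
) -> GradientSet:
    if modality == "functional":
        return embed_functional(group_cm, params)
    return embed_structural(group_cm, scheme, params)


def build_template(
    study: Sequence["SubjectRecord"],
    spec: TemplateSpec,
    modality: str = "functional",
    reference: Sequence["SubjectRecord"] | None = None,
    scheme: ParcellationScheme | None = None,
    params: GradientParams | None = None,
) -> GradientSet:
    """Construct the group-level template for one strategy.

    Strategies 1-3 embed a group matrix built from the corresponding
    subject selection of the study cohort; strategy 4 embeds the
    reference cohort; strategies 5 and 6 build the strategy-1/2 template
    and rotate it onto the strategy-4 template (the rotated gradients are
    the returned template).
    """
    params = params or GradientParams()
    if spec.uses_reference and not reference:
        raise ValueError(f"strategy {spec.strategy} requires a reference cohort")

    if spec.strategy in (5, 6):
        base = build_template(
            study,
            TemplateSpec(spec.strategy - 4),
            modality=modality,
            scheme=scheme,
            params=params,
        )
        ref_template = build_template(
            study,
            TemplateSpec(4),
            modality=modality,
            reference=reference,
            scheme=scheme,
            params=params,
        )
        aligned, _ = procrustes_rotate(base.components, ref_template.components)
        out = base.copy_with(aligned)
        out.meta["strategy"] = spec.strategy
        return out

    if spec.strategy == 4:
        selection = list(reference or [])
    else:
        wanted = {
            1: ("case", "control"),
            2: ("control",),
            3: ("case",),
        }[spec.strategy]
        selection = [s for s in study if s.group in wanted]
    if not selection:
        raise ValueError(f"strategy {spec.strategy}: empty subject selection")

    group_cm = group_connectivity(selection, modality, scheme=scheme)
    out = _embed_group(group_cm, modality, scheme, params)
    out.meta["strategy"] = spec.strategy
    return out
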