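"""Synthetic connectome cohorts with planted lesion and behavior structure.

The generator emulates the statistical shape the downstream analysis
assumes, not brain anatomy:

* each subject is a degree-heterogeneous weighted block model with two
  hemisphere-like super-blocks, each split into equal modules; within-module
  edges are dense and heavy, between-module edges (within a hemisphere)
  light, cross-hemisphere background edges sparse and lighter still, and one
  designated node per module carries a strong homotopic *bridge* edge to its
  mirror node in the opposite hemisphere;
* a lesion deletes a random fraction of the nodes of one super-block
  (zeroing their rows/columns) and attenuates the surviving edges incident
  to that block, mimicking a left-hemisphere stroke's effect on streamline
  counts;
* behavioral scores for lesioned subjects are drawn with a planted negative
  linear dependence of the phonological-error proportion on the normalized
  boundary-controllability rank of the designated contralesional bridge
  node (the right-hemisphere mirror of the first left module's bridge), a
  semantic-error proportion independent of controllability, and severity /
  naming-accuracy scores driven by lesion load.

Label names reuse the atlas dialect of the real data (``rh.parstriangularis``
etc.) so the same region configuration resolves on synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controllability import bc_rank
from .io import Connectome

__all__ = [
    "LesionSpec",
    "BehaviorSpec",
    "SyntheticCohortSpec",
    "generate_connectome",
    "apply_lesion",
    "generate_behavior",
    "generate_cohort",
    "LesionRecord",
]


@dataclass
class LesionSpec:
    """Where and how hard the simulated stroke hits."""

    target: str = "left"              # super-block to damage
    node_fraction: float = 0.3        # fraction of target nodes removed
    attenuation: float = 0.5          # multiplier on surviving target-incident edges

    def __post_init__(self):
        if not 0.0 <= self.node_fraction <= 1.0:
            raise ValueError("node_fraction must be in [0, 1]")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must be in [0, 1]")
        if self.target not in ("left", "right"):
            raise ValueError("lesion target must be 'left' or 'right'")


@dataclass
class BehaviorSpec:
    """Planted behavior model for lesioned subjects.

    ``phon_err = clip(beta0 + beta1 * rank_norm + N(0, sigma))`` where
    ``rank_norm`` is the designated bridge node's BC rank divided by N.
    The baseline ``beta0`` is set so the planted linear relation stays
    strictly inside the unit interval over the achievable rank range
    (rank fractions up to 1.0 with slope -0.3 and 3-sigma noise); clipping
    would otherwise bend the generating model away from linearity.
    Semantic errors are drawn independently of controllability; severity
    (WAB-AQ) and naming accuracy are driven by lesion load with noise.
    """

    beta0: float = 0.5
    beta1: float = -0.3
    sigma: float = 0.05
    sem_mean: float = 0.17
    sem_sigma: float = 0.12


@dataclass
class SyntheticCohortSpec:
    """Block-model, lesion, and behavior-coupling parameters with a seed."""

    n_nodes: int = 60
    modules_per_hemisphere: int = 3
    within_weight_mean: float = 30.0
    between_weight_mean: float = 3.0
    bridge_weight_mean: float = 10.0
    cross_background_mean: float = 0.6
    weight_family: str = "poisson"     # or "negative_binomial"
    nb_dispersion: float = 2.0         # NB size parameter (smaller = more overdispersed)
    degree_sigma: float = 0.3          # lognormal sd of node propensities
    lesion: LesionSpec = field(default_factory=LesionSpec)
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    n_pwa: int = 60
    n_controls: int = 62
    n_pnt: int = 50                    # PWA subset with naming-test scores
    gamma: float = 1.5                 # resolution for generation-time BC
    bc_n_opt: int = 8                  # ensemble size for generation-time BC
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes % (2 * self.modules_per_hemisphere) != 0:
            raise ValueError(
                "n_nodes must be divisible by 2 * modules_per_hemisphere"
            )
        for name in ("within_weight_mean", "between_weight_mean", "bridge_weight_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.weight_family not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown weight_family {self.weight_family!r}")
        if min(self.n_pwa, self.n_controls) < 1:
            raise ValueError("n_pwa and n_controls must be >= 1")

    # -- derived geometry -------------------------------------------------
    @property
    def n_left(self) -> int:
        return self.n_nodes // 2

    @property
    def module_size(self) -> int:
        return self.n_left // self.modules_per_hemisphere

    def module_of(self, i: int) -> int:
        """Module index 0..2*modules_per_hemisphere-1 of node i."""
        return i // self.module_size

    def hemisphere_of(self, i: int) -> str:
        return "left" if i < self.n_left else "right"

    @property
    def bridge_pairs(self) -> list[tuple[int, int]]:
        """Designated homotopic pairs: first node of each left module and
        its mirror in the right hemisphere."""
        return [
            (m * self.module_size, self.n_left + m * self.module_size)
            for m in range(self.modules_per_hemisphere)
        ]

    @property
    def designated_node(self) -> int:
        """The contralesional bridge node the behavior model couples to
        (plays the role of the right pars triangularis)."""
        return self.n_left

    def labels(self) -> list[str]:
        """Atlas-dialect labels; special names on the analysis targets."""
        special = {
            self.designated_node: "rh.parstriangularis_1",
            self.designated_node + 1: "rh.parsopercularis_1",
            self.n_nodes - 1: "rh.lateraloccipital_1",
        }
        out = []
        for i in range(self.n_nodes):
            if i in special:
                out.append(special[i])
            else:
                hemi = "lh" if i < self.n_left else "rh"
                m = self.module_of(i) % self.modules_per_hemisphere
                out.append(f"{hemi}.mod{chr(ord('a') + m)}_{i % self.module_size + 1}")
        return out


def _draw_counts(mean: np.ndarray, spec: SyntheticCohortSpec, rng) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    if spec.weight_family == "poisson":
        return rng.poisson(mean)
    r = spec.nb_dispersion
    p = r / (r + mean)
    out = np.where(mean > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
    return out


def generate_connectome(spec: SyntheticCohortSpec, subject_seed, subject_id="syn", group="control") -> Connectome:
    """One subject's symmetric integer-weight block-model matrix."""
    rng = np.random.default_rng(subject_seed)
    n = spec.n_nodes
    u = rng.lognormal(mean=0.0, sigma=spec.degree_sigma, size=n)  # propensities
    mods = np.array([spec.module_of(i) for i in range(n)])
    hemi = np.array([0 if i < spec.n_left else 1 for i in range(n)])
    same_mod = mods[:, None] == mods[None, :]
    same_hemi = hemi[:, None] == hemi[None, :]
    base = np.where(
        same_mod, spec.within_weight_mean,
        np.where(same_hemi, spec.between_weight_mean, spec.cross_background_mean),
    ).astype(float)
    for a, b in spec.bridge_pairs:
        base[a, b] = base[b, a] = spec.bridge_weight_mean
    mean = base * np.outer(u, u)
    np.fill_diagonal(mean, 0.0)
    W = _draw_counts(mean, spec, rng).astype(float)
    W = np.triu(W, k=1)
    W = W + W.T
    return Connectome(subject_id=subject_id, group=group, labels=spec.labels(), weights=W)


@dataclass
class LesionRecord:
    """What the simulated stroke removed."""

    removed_nodes: list[int]
    tlv: float                 # proxy: total edge-weight mass lost
    lesion_load: float         # tlv / pre-lesion total mass
    lptr_damage: float         # percent strength lost at the designated homotope


def apply_lesion(conn: Connectome, spec: SyntheticCohortSpec, seed) -> tuple[Connectome, LesionRecord]:
    """Delete a random fraction of one super-block and attenuate the rest.

    Selected nodes' rows/columns are zeroed; surviving edges with at least
    one endpoint in the targeted super-block are multiplied by the
    attenuation factor and re-rounded.  Returns the lesioned connectome and
    a record with the removed nodes and a lesion-volume proxy (the edge
    mass lost, which is monotone in the node fraction).
    """
    rng = np.random.default_rng(seed)
    les = spec.lesion
    n = conn.n_nodes
    target = (
        np.arange(spec.n_left) if les.target == "left" else np.arange(spec.n_left, n)
    )
    n_remove = int(round(les.node_fraction * len(target)))
    removed = np.sort(rng.choice(target, size=n_remove, replace=False))
    A = conn.weights.copy()
    pre_mass = A.sum() / 2.0
    homotope = spec.designated_node - spec.n_left  # left mirror of designated node
    pre_homotope_strength = A[homotope].sum()
    in_target = np.zeros(n, dtype=bool)
    in_target[target] = True
    touches = in_target[:, None] | in_target[None, :]
    A = np.where(touches, np.rint(A * les.attenuation), A)
    A[removed, :] = 0.0
    A[:, removed] = 0.0
    post_mass = A.sum() / 2.0
    post_homotope_strength = A[homotope].sum()
    rec = LesionRecord(
        removed_nodes=[int(i) for i in removed],
        tlv=float(pre_mass - post_mass),
        lesion_load=float((pre_mass - post_mass) / pre_mass) if pre_mass else 0.0,
        lptr_damage=float(
            100.0 * (1.0 - post_homotope_strength / pre_homotope_strength)
        ) if pre_homotope_strength else 0.0,
    )
    lesioned = Connectome(
        subject_id=conn.subject_id, group="PWA", labels=conn.labels, weights=A
    )
    return lesioned, rec


def generate_behavior(
    spec: SyntheticCohortSpec,
    rank_norms: np.ndarray,
    records: list[LesionRecord],
    rng: np.random.Generator,
    subject_ids: list[str],
) -> pd.DataFrame:
    """Behavioral table for lesioned subjects given their BC rank fractions."""
    beh = spec.behavior
    n = len(rank_norms)
    load = np.array([r.lesion_load for r in records])
    phon = np.clip(
        beh.beta0 + beh.beta1 * rank_norms + rng.normal(0, beh.sigma, n), 0, 1
    )
    sem = np.clip(rng.normal(beh.sem_mean, beh.sem_sigma, n), 0, 1)
    wab = np.clip(95.0 - 90.0 * load + rng.normal(0, 12.0, n), 0, 100)
    acc = np.clip(0.85 - 1.1 * load + rng.normal(0, 0.12, n), 0, 1)
    df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "wab_aq": wab,
            "pnt_accuracy": acc,
            "sem_err_prop": sem,
            "phon_err_prop": phon,
            "tlv": [r.tlv for r in records],
            "lptr_damage": [r.lptr_damage for r in records],
        }
    )
    # naming test administered to a subset only
    n_pnt = min(spec.n_pnt, n)
    without = rng.choice(n, size=n - n_pnt, replace=False)
    for col in ("pnt_accuracy", "sem_err_prop", "phon_err_prop"):
        df.loc[without, col] = np.nan
    return df


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[list[Connectome], pd.DataFrame, dict]:
    """Full cohort: unlesioned controls, lesioned PWA, behavior, and truth.

    The truth record stores the planted behavior coefficients and every
    per-subject quantity used in generation (designated-node rank, removed
    nodes, lesion load) so recovery can be verified downstream.
    """
    ss = np.random.SeedSequence(spec.seed)
    conn_seeds, lesion_seeds, bc_seeds, beh_seed = ss.spawn(4)
    conn_ss = conn_seeds.spawn(spec.n_controls + spec.n_pwa)
    lesion_ss = lesion_seeds.spawn(spec.n_pwa)
    bc_ss = bc_seeds.spawn(spec.n_pwa)

    connectomes: list[Connectome] = []
    for i in range(spec.n_controls):
        connectomes.append(
            generate_connectome(spec, conn_ss[i], subject_id=f"ctrl_{i:03d}", group="control")
        )
    records: list[LesionRecord] = []
    ranks = np.empty(spec.n_pwa)
    pwa_ids = [f"pwa_{i:03d}" for i in range(spec.n_pwa)]
    for i in range(spec.n_pwa):
        base = generate_connectome(
            spec, conn_ss[spec.n_controls + i], subject_id=pwa_ids[i], group="control"
        )
        lesioned, rec = apply_lesion(base, spec, lesion_ss[i])
        ranking = bc_rank(
            lesioned.weights,
            gamma=spec.gamma,
            n_opt=spec.bc_n_opt,
            seed=int(bc_ss[i].generate_state(1)[0] % 2**31),
        )
        ranks[i] = ranking.rank[spec.designated_node]
        connectomes.append(lesioned)
        records.append(rec)
    rank_norms = ranks / spec.n_nodes
    behavior = generate_behavior(
        spec, rank_norms, records, np.random.default_rng(beh_seed), pwa_ids
    )
    truth = {
        "beta0": spec.behavior.beta0,
        "beta1": spec.behavior.beta1,
        "sigma": spec.behavior.sigma,
        "designated_node": spec.designated_node,
        "gamma": spec.gamma,
        "subject_ids": pwa_ids,
        "designated_rank": ranks.tolist(),
        "rank_norm": rank_norms.tolist(),
        "removed_nodes": [r.removed_nodes for r in records],
        "lesion_load": [r.lesion_load for r in records],
    }
    return connectomes, behavior, truth
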