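"""Reading and writing connectomes, cohort manifests, and behavioral tables.

File dialects
-------------
* Connectome: delimited numeric text (comma or tab, autodetected), no
  header, one row per node; streamline counts, symmetric, zero diagonal.
* Labels: one parcel name per line, in node order.
* Manifest: CSV with header ``subject_id,group,connectome_path`` and an
  optional ``included_in_pnt`` column; paths are resolved relative to the
  manifest's directory.
* Behavioral table: CSV with header, one row per person with aphasia:
  ``subject_id,wab_aq,pnt_accuracy,sem_err_prop,phon_err_prop,tlv,
  lptr_damage``.  Picture-naming columns may be empty (the naming test was
  administered to a subset only).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "read_connectome",
    "write_connectome",
    "resolve_regions",
    "read_cohort",
    "write_cohort",
    "validate_behavior",
]

GROUPS = ("PWA", "control")
#: relative asymmetry above this indicates a corrupt file
ASYMMETRY_TOL = 1e-8

BEHAVIOR_COLUMNS = [
    "subject_id",
    "wab_aq",
    "pnt_accuracy",
    "sem_err_prop",
    "phon_err_prop",
    "tlv",
    "lptr_damage",
]
PNT_COLUMNS = ["pnt_accuracy", "sem_err_prop", "phon_err_prop"]


@dataclass
class Connectome:
    """One subject's weighted structural network.

    ``weights[i, j]`` is the streamline count between parcels ``i`` and
    ``j``; the matrix is symmetric, nonnegative, with zero diagonal.
    """

    subject_id: str
    group: str
    labels: list[str]
    weights: np.ndarray

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        A = np.asarray(self.weights, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"weights must be square, got shape {A.shape}")
        if len(self.labels) != len(A):
            raise ValueError(
                f"{len(self.labels)} labels for a {len(A)}-node matrix"
            )
        if np.isnan(A).any():
            raise ValueError("NaN in connectome weights")
        if (A < 0).any():
            raise ValueError("negative weight in connectome")
        if np.diagonal(A).any():
            raise ValueError("connectome diagonal must be zero")
        scale = A.max()
        if scale > 0:
            asym = np.abs(A - A.T).max() / scale
            if asym > ASYMMETRY_TOL:
                raise ValueError(
                    f"asymmetry {asym:.3g} exceeds tolerance {ASYMMETRY_TOL}"
                )
            A = (A + A.T) / 2.0
        self.weights = A

    @property
    def n_nodes(self) -> int:
        return len(self.weights)

    def strengths(self) -> np.ndarray:
        return self.weights.sum(axis=1)


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0]
    if "," in first:
        return ","
    if "\t" in first:
        return "\t"
    return " "


def read_connectome(path, labels_path, subject_id: str, group: str) -> Connectome:
    """Load and validate one delimited-text connectome."""
    path, labels_path = Path(path), Path(labels_path)
    delim = _sniff_delimiter(path)
    A = np.loadtxt(path, delimiter=None if delim == " " else delim, ndmin=2)
    labels = [ln.strip() for ln in labels_path.read_text().splitlines() if ln.strip()]
    return Connectome(subject_id=subject_id, group=group, labels=labels, weights=A)


def write_connectome(conn: Connectome, path, labels_path=None) -> None:
    """Write the weight matrix (TSV) and optionally the label file.

    Integer counts are written without a fractional part so that a
    write -> read round trip is bit-identical.
    """
    A = conn.weights
    if np.allclose(A, np.round(A)):
        np.savetxt(path, A.astype(np.int64), fmt="%d", delimiter="\t")
    else:
        np.savetxt(path, A, fmt="%.17g", delimiter="\t")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(conn.labels) + "\n")


def resolve_regions(labels: list[str], target_spec: dict[str, str]) -> dict[str, list[int]]:
    """Map named region targets to node indices via label patterns.

    ``target_spec`` maps a target name (e.g. ``rPTr``) to a regular
    expression searched against each parcel label.  All matching indices
    are returned; a pattern with zero matches is an error.
    """
    out: dict[str, list[int]] = {}
    for name, pattern in target_spec.items():
        rx = re.compile(pattern)
        hits = [i for i, lab in enumerate(labels) if rx.search(lab)]
        if not hits:
            raise KeyError(f"region pattern {pattern!r} for {name!r} matched no label")
        out[name] = hits
    return out


def validate_behavior(behavior: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, ranges, and uniqueness of the behavioral table."""
    missing = set(BEHAVIOR_COLUMNS) - set(behavior.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    if behavior["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in behavior table")
    for col in ("pnt_accuracy", "sem_err_prop", "phon_err_prop"):
        vals = behavior[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    wab = behavior["wab_aq"].dropna()
    if ((wab < 0) | (wab > 100)).any():
        raise ValueError("wab_aq outside [0, 100]")
    return behavior


def read_cohort(manifest_path, behavior_path) -> tuple[list[Connectome], pd.DataFrame]:
    """Load every subject in a manifest plus the PWA behavioral table.

    The behavioral table is joined on ``subject_id``; a behavior row with
    no matching manifest subject is an error.  Subjects with any missing
    picture-naming field get ``included_in_pnt = False``.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if manifest["subject_id"].duplicated().any():
        dups = manifest.loc[manifest["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subject ids in manifest: {sorted(set(dups))}")
    behavior = validate_behavior(pd.read_csv(behavior_path))
    unknown = set(behavior["subject_id"]) - set(manifest["subject_id"])
    if unknown:
        raise ValueError(f"behavior rows with no manifest subject: {sorted(unknown)}")

    base = manifest_path.parent
    connectomes = []
    for row in manifest.itertuples(index=False):
        cpath = base / row.connectome_path
        lpath = base / getattr(row, "labels_path", "labels.txt")
        connectomes.append(
            read_connectome(cpath, lpath, subject_id=row.subject_id, group=row.group)
        )
    behavior = behavior.copy()
    behavior["included_in_pnt"] = ~behavior[PNT_COLUMNS].isna().any(axis=1)
    n_pwa = sum(c.group == "PWA" for c in connectomes)
    n_ctl = len(connectomes) - n_pwa
    logger.info(
        "loaded cohort: %d PWA / %d controls (%d with naming data)",
        n_pwa, n_ctl, int(behavior["included_in_pnt"].sum()),
    )
    return connectomes, behavior


def write_cohort(connectomes: list[Connectome], behavior: pd.DataFrame, out_dir) -> Path:
    """Write connectome TSVs, a shared label file, manifest, and behavior CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = connectomes[0].labels
    (out / "labels.txt").write_text("\n".join(labels) + "\n")
    rows = []
    for conn in connectomes:
        fname = f"{conn.subject_id}.tsv"
        write_connectome(conn, out / fname)
        rows.append(
            {"subject_id": conn.subject_id, "group": conn.group,
             "connectome_path": fname, "labels_path": "labels.txt"}
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    behavior.to_csv(out / "behavior.csv", index=False)
    return out
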