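"""Data model and IO for urinary-peptide intensity datasets and panel fixtures.

The on-disk interchange format is a plain UTF-8 TSV: one row per sample, a
``sample_id`` column, a ``group`` column, optional ``etiology`` and clinical
covariate columns, then one column per peptide holding a nonnegative
normalized signal intensity (0 = peptide not detected in that sample).
Dataset-level metadata travels in an optional JSON side-car.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("pFSGS", "sFSGS", "NC", "CKD_other")
"""Closed vocabulary of cohort labels."""

#: Columns that are sample metadata rather than peptide intensities.
COVARIATE_COLUMNS = ("proteinuria", "egfr", "age", "sex", "ifta")
_META_COLUMNS = ("sample_id", "group", "etiology") + COVARIATE_COLUMNS

_SEQUENCE_RE = re.compile(r"[A-Zpm]+")  # lowercase p/m mark PTM residues


class DataError(ValueError):
    """Raised for malformed datasets, fixtures or intensity files."""


@dataclass(frozen=True)
class PanelPeptide:
    """One sequenced urinary peptide of the diagnostic panel.

    ``sequence`` uses uppercase one-letter residues plus two lowercase PTM
    markers: ``p`` for hydroxyproline and ``m`` for oxidized methionine.
    The three p-values correspond to the three discovery comparisons
    (cases vs normal controls, adjusted; cases vs disease controls,
    unadjusted) and the four means are group mean signal intensities in
    arbitrary normalized units.
    """

    peptide_id: str
    sequence: str
    protein_name: str
    p_step1: float
    p_step2: float
    p_step3: float
    mean_pfsgs: float
    mean_nc: float
    mean_sfsgs: float
    mean_ckd: float

    def __post_init__(self) -> None:
        if not _SEQUENCE_RE.fullmatch(self.sequence):
            raise DataError(
                f"peptide {self.peptide_id}: sequence {self.sequence!r} "
                "contains characters outside [A-Zpm]"
            )
        for name in ("p_step1", "p_step2", "p_step3"):
            p = getattr(self, name)
            if not 0.0 < p <= 1.0:
                raise DataError(f"peptide {self.peptide_id}: {name}={p} outside (0, 1]")
        for name in ("mean_pfsgs", "mean_nc", "mean_sfsgs", "mean_ckd"):
            if getattr(self, name) < 0:
                raise DataError(f"peptide {self.peptide_id}: negative {name}")

    def group_mean(self, group: str) -> float:
        """Mean signal intensity of this peptide in ``group``."""
        key = {
            "pFSGS": "mean_pfsgs",
            "NC": "mean_nc",
            "sFSGS": "mean_sfsgs",
            "CKD_other": "mean_ckd",
        }[group]
        return getattr(self, key)


@dataclass
class IntensityDataset:
    """Samples-by-peptides intensity matrix with cohort labels.

    Attributes
    ----------
    sample_ids, peptide_ids
        Unique identifiers for rows and columns of ``intensities``.
    intensities
        ``(n_samples, n_peptides)`` float array, nonnegative; 0 encodes
        "peptide not detected".
    group
        Per-sample cohort label from :data:`GROUPS`.
    etiology
        Optional per-sample disease subcode for CKD_other samples.
    covariates
        Optional per-sample clinical covariates (DataFrame indexed like
        ``sample_ids``; columns from :data:`COVARIATE_COLUMNS`).
    """

    sample_ids: list[str]
    peptide_ids: list[str]
    intensities: np.ndarray
    group: list[str]
    etiology: list[str | None] | None = None
    covariates: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, m = self.intensities.shape
        if len(self.sample_ids) != n or len(self.peptide_ids) != m:
            raise DataError("intensity matrix shape does not match id lists")
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample_id")
        if len(set(self.peptide_ids)) != m:
            raise DataError("duplicate peptide_id")
        if len(self.group) != n:
            raise DataError("group labels do not match sample count")
        unknown = set(self.group) - set(GROUPS)
        if unknown:
            raise DataError(f"unknown group label(s): {sorted(unknown)}")
        if not np.isfinite(self.intensities).all():
            bad = np.argwhere(~np.isfinite(self.intensities))[0]
            raise DataError(
                f"non-finite intensity at sample {self.sample_ids[bad[0]]}, "
                f"peptide {self.peptide_ids[bad[1]]}"
            )
        if (self.intensities < 0).any():
            bad = np.argwhere(self.intensities < 0)[0]
            raise DataError(
                f"negative intensity at sample {self.sample_ids[bad[0]]}, "
                f"peptide {self.peptide_ids[bad[1]]}"
            )
        if self.covariates is not None:
            self.covariates = self.covariates.reindex(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise DataError(f"unknown group label: {group}")
        return np.array([g == group for g in self.group])

    def group_matrix(self, group: str) -> np.ndarray:
        """Intensity submatrix of all samples in ``group``."""
        return self.intensities[self.group_mask(group)]

    def subset_peptides(self, peptide_ids: Sequence[str]) -> "IntensityDataset":
        idx = {p: i for i, p in enumerate(self.peptide_ids)}
        missing = [p for p in peptide_ids if p not in idx]
        if missing:
            raise DataError(f"peptides not in dataset: {missing[:5]}")
        cols = [idx[p] for p in peptide_ids]
        return IntensityDataset(
            sample_ids=list(self.sample_ids),
            peptide_ids=list(peptide_ids),
            intensities=self.intensities[:, cols].copy(),
            group=list(self.group),
            etiology=list(self.etiology) if self.etiology is not None else None,
            covariates=self.covariates.copy() if self.covariates is not None else None,
            metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide-format frame: metadata columns then peptide columns."""
        df = pd.DataFrame({"sample_id": self.sample_ids, "group": self.group})
        if self.etiology is not None:
            df["etiology"] = [e if e is not None else "" for e in self.etiology]
        if self.covariates is not None:
            for col in self.covariates.columns:
                df[col] = self.covariates[col].to_numpy()
        inten = pd.DataFrame(
            self.intensities, columns=self.peptide_ids, index=df.index
        )
        return pd.concat([df, inten], axis=1)


def read_intensity_dataset(path: str | Path) -> IntensityDataset:
    """Read a wide-format intensity TSV written by :func:`write_intensity_dataset`.

    Raises :class:`DataError` with row/column coordinates for unparseable or
    negative intensity cells, duplicate sample ids, or unknown group labels.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip"
    )
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise DataError(f"{path}: missing required sample_id/group columns")
    peptide_cols = [c for c in df.columns if c not in _META_COLUMNS]
    for col in peptide_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.loc[bad, "sample_id"].iloc[0]
            raise DataError(
                f"{path}: unparseable intensity at sample {row}, peptide {col}"
            )
        df[col] = numeric
    matrix = df[peptide_cols].to_numpy(dtype=float)
    if np.isnan(matrix).any():
        i, j = np.argwhere(np.isnan(matrix))[0]
        raise DataError(
            f"{path}: missing intensity at sample {df['sample_id'].iloc[i]}, "
            f"peptide {peptide_cols[j]}"
        )
    if (matrix < 0).any():
        i, j = np.argwhere(matrix < 0)[0]
        raise DataError(
            f"{path}: negative intensity at sample {df['sample_id'].iloc[i]}, "
            f"peptide {peptide_cols[j]}"
        )
    etiology = None
    if "etiology" in df.columns:
        etiology = [
            None if (pd.isna(e) or e == "") else str(e) for e in df["etiology"]
        ]
    cov_cols = [c for c in COVARIATE_COLUMNS if c in df.columns]
    covariates = None
    if cov_cols:
        covariates = df[cov_cols].copy()
        covariates.index = df["sample_id"].tolist()
    metadata = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    return IntensityDataset(
        sample_ids=df["sample_id"].tolist(),
        peptide_ids=peptide_cols,
        intensities=matrix,
        group=df["group"].tolist(),
        etiology=etiology,
        covariates=covariates,
        metadata=metadata,
    )


def write_intensity_dataset(dataset: IntensityDataset, path: str | Path) -> None:
    """Write ``dataset`` as a wide TSV plus a JSON metadata side-car.

    Uses ``repr`` float formatting so a read/write cycle is bit-identical.
    """
    path = Path(path)
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format=None)
    if dataset.metadata:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(dataset.metadata, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("peptipanel.fixtures").joinpath(name)


def load_panel_fixture() -> list[PanelPeptide]:
    """Load the packaged 93-peptide diagnostic panel, in printed order."""
    with resources.as_file(_fixture_path("panel_peptides.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    peptides = [PanelPeptide(**row) for row in df.to_dict(orient="records")]
    if len(peptides) != 93:
        raise DataError(f"panel fixture corrupted: {len(peptides)} rows, expected 93")
    if len({p.peptide_id for p in peptides}) != len(peptides):
        raise DataError("panel fixture corrupted: duplicate peptide ids")
    return peptides


def load_etiology_fixture(which: str = "matched") -> dict[str, int]:
    """Etiology -> patient count for the ``matched`` or ``independent`` table."""
    name = {
        "matched": "etiologies_matched.json",
        "independent": "etiologies_independent.json",
    }[which]
    payload = json.loads(_fixture_path(name).read_text())
    return {code: entry["n"] for code, entry in payload["counts"].items()}


def load_cohort_characteristics() -> dict:
    """Per-group clinical summary statistics (n, mean/sd, median/IQR, counts)."""
    return json.loads(_fixture_path("cohort_characteristics.json").read_text())["groups"]


# ---------------------------------------------------------------------------
# Panel summary operations
# ---------------------------------------------------------------------------

def panel_protein_composition(
    panel: Sequence[PanelPeptide], protein_substring: str
) -> tuple[int, float]:
    """Count panel peptides whose protein name contains ``protein_substring``.

    Returns ``(count, percent)`` with the percentage of the panel reported
    to one decimal. The match is case-insensitive; the empty substring
    matches everything.
    """
    if not panel:
        raise DataError("panel is empty")
    needle = protein_substring.lower()
    count = sum(needle in p.protein_name.lower() for p in panel)
    percent = round(100.0 * count / len(panel), 1)
    return count, percent


def max_group_fold_change(
    panel: Sequence[PanelPeptide],
    protein_substring: str,
    numerator_group: str,
    denominator_group: str,
) -> float:
    """Largest per-peptide group-mean ratio among matching panel peptides.

    Matching is case-insensitive on token boundaries, so a query like
    ``"Apolipoprotein A-I"`` does not also select ``"Apolipoprotein A-IV"``
    peptides. Peptides whose denominator mean is exactly 0 are skipped
    (several normal-control means in the packaged panel are 0, which would
    otherwise make the ratio infinite).
    """
    pattern = re.compile(
        r"(?<![A-Za-z0-9])" + re.escape(protein_substring) + r"(?![A-Za-z0-9])",
        re.IGNORECASE,
    )
    ratios = []
    for p in panel:
        if not pattern.search(p.protein_name):
            continue
        denom = p.group_mean(denominator_group)
        if denom == 0:
            continue
        ratios.append(p.group_mean(numerator_group) / denom)
    if not ratios:
        raise DataError(
            f"no peptide matching {protein_substring!r} with nonzero "
            f"{denominator_group} mean"
        )
    return max(ratios)


def etiology_table_total(table: Mapping[str, int] | Iterable[int]) -> int:
    """Total patient count of an etiology table (sum of the N column)."""
    counts = list(table.values()) if isinstance(table, Mapping) else list(table)
    if any(c < 0 for c in counts):
        raise DataError("negative etiology count")
    return int(sum(counts))
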