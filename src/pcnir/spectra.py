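"""Containers and delimited-text I/O for NIR spectra and sample metadata.

The two in-memory types mirror the X / Y structure of a quantitative NIR
study: :class:`SpectraMatrix` holds an absorbance block over a strictly
ascending wavenumber axis (cm^-1), :class:`SampleTable` holds per-sample
cultivation-region labels and reference chemistry values (mg g^-1).

On-disk formats are plain delimited text: a matrix CSV whose header row is
``sample_id,<wn1>,<wn2>,...`` for spectra, and a flat CSV for the sample
table.  A minimal read-only JCAMP-DX reader (AFFN ``XYDATA=(X++(Y..Y))``)
is provided for single instrument exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Cultivation-region codes: Yunnan, Xiangqian, Dabie Mountains.
REGIONS = ("YN", "XQ", "DBM")

#: The five triterpene acids quantified by HPLC.
TRITERPENE_ACIDS = ("dtua", "paa", "pac", "dpa", "dtra")

#: All chemistry columns of the sample table, in canonical order.
CHEMISTRY_COLUMNS = ("psc", "wse", "ase") + TRITERPENE_ACIDS + ("sft",)

#: The four quality parameters modelled quantitatively.
QUALITY_PARAMETERS = ("psc", "wse", "ase", "sft")


def nm_to_wavenumber(nm):
    """Convert wavelength in nm to wavenumber in cm^-1 (and vice versa)."""
    return 1.0e7 / np.asarray(nm, dtype=float)


@dataclass
class SpectraMatrix:
    """Samples x wavenumbers absorbance block with a shared ascending axis.

    Parameters
    ----------
    wavenumbers
        Strictly ascending spectral positions in cm^-1, length ``p``.
    absorbance
        ``(n, p)`` array of finite absorbance values.
    sample_ids
        ``n`` unique sample identifiers.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavenumbers.size < 1:
            raise ValidationError("empty wavenumber axis")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValidationError("wavenumbers must be strictly ascending")
        n, p = self.absorbance.shape
        if p != self.wavenumbers.size:
            raise ValidationError(
                f"absorbance has {p} columns but axis has {self.wavenumbers.size}"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} absorbance rows"
            )
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(self.absorbance)):
            bad = [self.sample_ids[i] for i in
                   sorted(set(np.argwhere(~np.isfinite(self.absorbance))[:, 0]))]
            raise ValidationError(f"non-finite absorbance in samples {bad}")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(self.wavenumbers.copy(), self.absorbance.copy(),
                             list(self.sample_ids))

    def with_absorbance(self, values) -> "SpectraMatrix":
        """Same axis and ids, new absorbance block (post-pretreatment)."""
        return SpectraMatrix(self.wavenumbers.copy(), np.asarray(values, float),
                             list(self.sample_ids))

    def subset(self, ids: Sequence[str]) -> "SpectraMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in ids]
        return SpectraMatrix(self.wavenumbers.copy(), self.absorbance[rows],
                             list(ids))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.absorbance, columns=self.wavenumbers)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class SampleTable:
    """Per-sample region label and reference chemistry values.

    Wraps a DataFrame with columns ``sample_id``, ``region`` and any of
    the chemistry columns (mg g^-1); missing values are permitted.  When
    the five triterpene acids are all present and ``sft`` is absent it is
    recomputed as their sum; when both are present they must agree to
    1e-9.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        for col in ("sample_id", "region"):
            if col not in df.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise ValidationError(f"duplicate sample ids: {dupes}")
        bad = sorted(set(df["region"]) - set(REGIONS))
        if bad:
            raise ValidationError(
                f"unknown region labels {bad}; allowed labels are {list(REGIONS)}"
            )
        for col in CHEMISTRY_COLUMNS:
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                if vals.isna().sum() > df[col].isna().sum():
                    raise ValidationError(f"non-numeric values in column {col!r}")
                if (vals.dropna() < 0).any():
                    raise ValidationError(f"negative concentrations in {col!r}")
                df[col] = vals
            else:
                df[col] = np.nan
        acids = df[list(TRITERPENE_ACIDS)]
        have_acids = acids.notna().all(axis=1)
        acid_sum = acids.sum(axis=1)
        fill = have_acids & df["sft"].isna()
        df.loc[fill, "sft"] = acid_sum[fill]
        check = have_acids & df["sft"].notna()
        off = check & ((df["sft"] - acid_sum).abs() > 1e-9)
        if off.any():
            raise ValidationError(
                "sft disagrees with the sum of the five acids for samples "
                f"{sorted(df.loc[off, 'sample_id'])}"
            )
        self.data = df[["sample_id", "region", *CHEMISTRY_COLUMNS]].reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    @property
    def regions(self) -> np.ndarray:
        return self.data["region"].to_numpy()

    def response(self, name: str) -> np.ndarray:
        """Reference values for one chemistry column, aligned to sample order."""
        if name not in CHEMISTRY_COLUMNS:
            raise ValidationError(f"unknown response {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def subset(self, ids: Sequence[str]) -> "SampleTable":
        indexed = self.data.set_index("sample_id")
        missing = [s for s in ids if s not in indexed.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return SampleTable(indexed.loc[list(ids)].reset_index())

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_spectra(path, dialect: str = "matrix-csv") -> SpectraMatrix:
    """Read a spectra file into a :class:`SpectraMatrix`.

    ``matrix-csv`` expects a header ``sample_id,<wn1>,<wn2>,...``; columns
    may be written in any order and are re-sorted to an ascending axis.
    ``jcamp-dx`` reads a single AFFN-encoded spectrum.
    """
    if dialect == "matrix-csv":
        return _read_matrix_csv(path)
    if dialect == "jcamp-dx":
        return _read_jcamp(path)
    raise ValidationError(
        f"unknown dialect {dialect!r}; expected 'matrix-csv' or 'jcamp-dx'"
    )


def _read_matrix_csv(path) -> SpectraMatrix:
    try:
        df = pd.read_csv(path, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "sample_id":
        raise ParseError(f"{path}: expected header 'sample_id,<wn1>,...'")
    try:
        wn = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric wavenumber column: {exc}") from exc
    block = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if np.isnan(block).any():
        r, c = np.argwhere(np.isnan(block))[0]
        raise ValidationError(
            f"{path}: non-numeric absorbance for sample "
            f"{df.iloc[r, 0]!r} at wavenumber {wn[c]:g}"
        )
    order = np.argsort(wn)
    return SpectraMatrix(wn[order], block[:, order], list(df.iloc[:, 0]))


def _read_jcamp(path) -> SpectraMatrix:
    """Minimal JCAMP-DX reader: AFFN ``##XYDATA=(X++(Y..Y))`` blocks only."""
    text = Path(path).read_text().splitlines()
    headers = {}
    data_lines = []
    in_data = False
    for lineno, line in enumerate(text, 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise ParseError(
                        f"{path}:{lineno}: only (X++(Y..Y)) XYDATA supported"
                    )
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            headers[key] = value.strip()
        elif in_data:
            data_lines.append((lineno, line))
    if not data_lines:
        raise ParseError(f"{path}: no XYDATA block found")
    try:
        npoints = int(float(headers["NPOINTS"]))
        firstx = float(headers["FIRSTX"])
        lastx = float(headers["LASTX"])
    except KeyError as exc:
        raise ParseError(f"{path}: missing required header ##{exc.args[0]}") from exc
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    ys = []
    for lineno, line in enumerate_affn(data_lines, path):
        ys.extend(line)
    if len(ys) != npoints:
        raise ParseError(
            f"{path}: NPOINTS={npoints} but {len(ys)} ordinates decoded"
        )
    x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    y = np.array(ys) * yfactor
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    title = headers.get("TITLE", Path(path).stem) or Path(path).stem
    return SpectraMatrix(x, y[np.newaxis, :], [title])


def enumerate_affn(data_lines, path):
    """Yield decoded ordinate lists for AFFN data lines (x value dropped)."""
    for lineno, line in data_lines:
        fields = line.replace(",", " ").split()
        try:
            values = [float(f) for f in fields]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-AFFN datum: {exc}") from exc
        if len(values) < 2:
            raise ParseError(f"{path}:{lineno}: data line without ordinates")
        yield lineno, values[1:]


def read_sample_table(path) -> SampleTable:
    """Read a sample metadata CSV (``sample_id,region,psc,...,sft``)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"could not parse {path}: {exc}") from exc
    return SampleTable(df)


def average_replicates(spectra: SpectraMatrix,
                       replicate_of: Mapping[str, str]) -> SpectraMatrix:
    """Average replicate scans into one spectrum per specimen.

    ``replicate_of`` maps every sample_id to its specimen id; output rows
    are arithmetic means of each specimen's replicates, in first-appearance
    order of the specimen ids.
    """
    missing = [s for s in spectra.sample_ids if s not in replicate_of]
    if missing:
        raise ValidationError(f"samples without replicate annotation: {missing}")
    order = []
    groups: dict = {}
    for i, sid in enumerate(spectra.sample_ids):
        spec = str(replicate_of[sid])
        if spec not in groups:
            groups[spec] = []
            order.append(spec)
        groups[spec].append(i)
    rows = [spectra.absorbance[groups[spec]].mean(axis=0) for spec in order]
    return SpectraMatrix(spectra.wavenumbers.copy(), np.vstack(rows), order)
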