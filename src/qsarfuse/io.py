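"""Data model and CSV readers/writers shared by all stages.

The central container is :class:`PredictionTable`: a chemicals x models
matrix of class votes, an applicability-domain (AD) mask of identical shape,
experimental labels, and optional SMILES. Votes and labels are stored as
small integer codes (``ACTIVE``/``INACTIVE``/``NO_PREDICTION``/``UNKNOWN``)
so that consensus computations over tens of thousands of chemicals and tens
of models stay vectorised; the string vocabulary only appears at the CSV
boundary.

A vote is counted downstream only where the AD mask is true: an out-of-AD
entry is treated identically to an explicit "no-prediction". That equivalence
is enforced centrally by :meth:`PredictionTable.effective_votes`, which every
downstream module consumes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("qsarfuse")

# Integer codes for votes / labels. UNKNOWN shares the -1 slot with
# NO_PREDICTION deliberately: both mean "no usable class here".
ACTIVE: int = 1
INACTIVE: int = 0
NO_PREDICTION: int = -1
UNKNOWN: int = -1

ACTIVE_TOKEN = "active"
INACTIVE_TOKEN = "inactive"
NO_PREDICTION_TOKEN = "no-prediction"
NOT_PREDICTED_TOKEN = "not-predicted"
UNKNOWN_TOKEN = "unknown"

_VOTE_ALIASES = {
    ACTIVE_TOKEN: ACTIVE,
    INACTIVE_TOKEN: INACTIVE,
    NO_PREDICTION_TOKEN: NO_PREDICTION,
    NOT_PREDICTED_TOKEN: NO_PREDICTION,
    "": NO_PREDICTION,
    "na": NO_PREDICTION,
    "nan": NO_PREDICTION,
}

_LABEL_ALIASES = {
    ACTIVE_TOKEN: ACTIVE,
    INACTIVE_TOKEN: INACTIVE,
    UNKNOWN_TOKEN: UNKNOWN,
    "": UNKNOWN,
    "na": UNKNOWN,
    "nan": UNKNOWN,
}

_TRUE_STRINGS = {"true", "t", "1", "yes", "in"}
_FALSE_STRINGS = {"false", "f", "0", "no", "out"}


def vote_to_token(code: int) -> str:
    """Render a vote code with the external vocabulary."""
    if code == ACTIVE:
        return ACTIVE_TOKEN
    if code == INACTIVE:
        return INACTIVE_TOKEN
    return NO_PREDICTION_TOKEN


def label_to_token(code: int) -> str:
    if code == ACTIVE:
        return ACTIVE_TOKEN
    if code == INACTIVE:
        return INACTIVE_TOKEN
    return UNKNOWN_TOKEN


def normalize_vote(raw: str, *, row: object = "?", column: object = "?") -> int:
    """Map a raw CSV cell to a vote code, case-insensitively and ignoring
    surrounding whitespace. Unrecognised values raise, naming the offending
    row and column."""
    key = str(raw).strip().lower()
    try:
        return _VOTE_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unrecognised vote value {raw!r} at row {row}, column {column}; "
            f"expected one of {sorted(k for k in _VOTE_ALIASES if k)}"
        ) from None


def normalize_label(raw: str, *, row: object = "?") -> int:
    key = str(raw).strip().lower()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unrecognised experimental label {raw!r} at row {row}; "
            f"expected active/inactive/unknown"
        ) from None


@dataclass
class DatasetSummary:
    """Class composition of a labelled set: total count and per-class counts.

    ``n_active + n_inactive`` may be less than ``n`` when some chemicals
    carry no experimental label; class proportions (used e.g. for
    proportional Bayes priors) are taken over the labelled subset.
    """

    n: int
    n_active: int
    n_inactive: int

    @property
    def n_labeled(self) -> int:
        return self.n_active + self.n_inactive

    def prevalence_active(self) -> float:
        """Percentage of actives among labelled chemicals."""
        if self.n_labeled == 0:
            raise ValueError("no labelled chemicals: prevalence undefined")
        return 100.0 * self.n_active / self.n_labeled

    def class_priors(self) -> np.ndarray:
        """(p_active, p_inactive) proportional to the labelled class counts."""
        if self.n_labeled == 0:
            raise ValueError("no labelled chemicals: proportional prior undefined")
        return np.array([self.n_active, self.n_inactive], dtype=float) / self.n_labeled


@dataclass
class ConsensusConfig:
    """Configuration of a consensus run.

    method
        ``MVL`` / ``MVI`` / ``MVS`` — majority voting with agreement
        strictly > 50 %, >= 75 %, and = 100 % respectively; ``B`` — Bayes
        consensus; ``Bp`` — protective Bayes (assign only when the maximum
        posterior reaches ``posterior_threshold``).
    agreement_threshold
        Majority-class agreement required by the MV modes; filled from the
        method's canonical value when left ``None``.
    posterior_threshold
        Posterior probability required by ``Bp`` (default 0.95).
    prior_mode
        ``equal`` (0.50 / 0.50) or ``proportional`` (labelled class counts).
    smoothing_alpha
        Pseudocount added to each confusion-matrix cell pair when estimating
        likelihoods, keeping them strictly inside (0, 1).
    min_votes
        Minimum number of in-AD votes a chemical needs before any class can
        be assigned.
    """

    method: str = "MVL"
    agreement_threshold: float | None = None
    posterior_threshold: float = 0.95
    prior_mode: str = "equal"
    smoothing_alpha: float = 0.5
    min_votes: int = 1

    _MV_DEFAULTS = {"MVL": 0.5, "MVI": 0.75, "MVS": 1.0}
    METHODS = ("MVL", "MVI", "MVS", "B", "Bp")

    def __post_init__(self) -> None:
        if self.method not in self.METHODS:
            raise ValueError(f"unknown consensus method {self.method!r}; expected one of {self.METHODS}")
        if not (0.5 < self.posterior_threshold <= 1.0):
            raise ValueError("posterior_threshold must lie in (0.5, 1]")
        if self.prior_mode not in ("equal", "proportional"):
            raise ValueError("prior_mode must be 'equal' or 'proportional'")
        if self.smoothing_alpha < 0:
            raise ValueError("smoothing_alpha must be nonnegative")
        if self.min_votes < 1:
            raise ValueError("min_votes must be a positive integer")
        if self.agreement_threshold is None:
            self.agreement_threshold = self._MV_DEFAULTS.get(self.method, 0.5)
        elif self.method in self._MV_DEFAULTS and not (0.5 <= self.agreement_threshold <= 1.0):
            raise ValueError("agreement_threshold must lie in [0.5, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PredictionTable:
    """Chemicals x models matrix of class votes with AD mask and labels.

    Invariants (checked at construction): votes and ad_mask share their
    shape; chemical ids and model names are unique; vote and label codes are
    drawn from the declared vocabulary.
    """

    chemical_ids: list[str]
    model_names: list[str]
    votes: np.ndarray          # (n_chemicals, n_models) int8
    ad_mask: np.ndarray        # (n_chemicals, n_models) bool
    true_labels: np.ndarray    # (n_chemicals,) int8
    smiles: list[str] | None = None

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=np.int8)
        self.ad_mask = np.asarray(self.ad_mask, dtype=bool)
        self.true_labels = np.asarray(self.true_labels, dtype=np.int8)
        n, m = len(self.chemical_ids), len(self.model_names)
        if self.votes.shape != (n, m):
            raise ValueError(f"votes shape {self.votes.shape} does not match ({n}, {m})")
        if self.ad_mask.shape != (n, m):
            raise ValueError(f"ad_mask shape {self.ad_mask.shape} does not match votes shape ({n}, {m})")
        if self.true_labels.shape != (n,):
            raise ValueError("true_labels must have one entry per chemical")
        if len(set(self.chemical_ids)) != n:
            raise ValueError("duplicate chemical ids")
        if len(set(self.model_names)) != m:
            raise ValueError("duplicate model names")
        if self.smiles is not None and len(self.smiles) != n:
            raise ValueError("smiles must have one entry per chemical")
        bad = ~np.isin(self.votes, (ACTIVE, INACTIVE, NO_PREDICTION))
        if bad.any():
            raise ValueError("votes contain codes outside {active, inactive, no-prediction}")
        bad = ~np.isin(self.true_labels, (ACTIVE, INACTIVE, UNKNOWN))
        if bad.any():
            raise ValueError("true_labels contain codes outside {active, inactive, unknown}")

    @property
    def n_chemicals(self) -> int:
        return len(self.chemical_ids)

    @property
    def n_models(self) -> int:
        return len(self.model_names)

    def effective_votes(self) -> np.ndarray:
        """Votes with out-of-AD entries replaced by ``NO_PREDICTION``.

        All downstream computations consume this view, which makes
        "AD mask false" and "vote = no-prediction" indistinguishable.
        """
        out = self.votes.copy()
        out[~self.ad_mask] = NO_PREDICTION
        return out

    def select_models(self, which: Sequence[int] | Sequence[str]) -> "PredictionTable":
        """Restrict to a subset (and ordering) of models, by index or name."""
        if len(which) == 0:
            raise ValueError("model subset must be non-empty")
        if isinstance(which[0], str):
            name_to_idx = {name: i for i, name in enumerate(self.model_names)}
            idx = [name_to_idx[w] for w in which]
        else:
            idx = list(which)
        return PredictionTable(
            chemical_ids=list(self.chemical_ids),
            model_names=[self.model_names[i] for i in idx],
            votes=self.votes[:, idx].copy(),
            ad_mask=self.ad_mask[:, idx].copy(),
            true_labels=self.true_labels.copy(),
            smiles=list(self.smiles) if self.smiles is not None else None,
        )

    def summary(self) -> DatasetSummary:
        return DatasetSummary(
            n=self.n_chemicals,
            n_active=int(np.sum(self.true_labels == ACTIVE)),
            n_inactive=int(np.sum(self.true_labels == INACTIVE)),
        )


@dataclass
class TableSchema:
    """Column-role mapping for prediction-table CSVs.

    Vote columns are recognised by ``vote_suffix`` (the model name is the
    stem); an AD column for model ``M`` is ``M + ad_suffix``. Missing AD
    columns default to all-true (a full-coverage model). Matching of
    suffixes is case-insensitive.
    """

    id_column: str = "chemical_id"
    smiles_column: str = "smiles"
    label_column: str = "true_label"
    vote_suffix: str = "_pred"
    ad_suffix: str = "_ad"

    @classmethod
    def from_file(cls, path: str | Path) -> "TableSchema":
        """Parse a plain ``key = value`` file mapping column roles."""
        kwargs: dict[str, str] = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown schema key {key!r}")
            kwargs[key] = value
        return cls(**kwargs)


def _parse_ad_cell(raw: str, *, row: object, column: str) -> bool:
    key = str(raw).strip().lower()
    if key in _TRUE_STRINGS:
        return True
    if key in _FALSE_STRINGS:
        return False
    raise ValueError(f"unrecognised AD flag {raw!r} at row {row}, column {column}")


def read_prediction_table(path: str | Path, schema: TableSchema | None = None) -> PredictionTable:
    """Read a prediction table from CSV.

    The CSV must carry a header; per-model vote columns (and optional AD
    columns) follow the naming convention declared in *schema*. Vote strings
    are normalised case-insensitively to {active, inactive, no-prediction};
    anything else raises, naming the offending row and column.
    """
    schema = schema or TableSchema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema.id_column not in df.columns:
        raise ValueError(f"missing id column {schema.id_column!r} in {path}")

    ids = [str(x).strip() for x in df[schema.id_column]]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate chemical ids in {path}: {dupes[:5]}")

    vote_suffix = schema.vote_suffix.lower()
    ad_suffix = schema.ad_suffix.lower()
    reserved = {schema.id_column, schema.smiles_column, schema.label_column}
    vote_cols: dict[str, str] = {}
    ad_cols: dict[str, str] = {}
    for col in df.columns:
        if col in reserved:
            continue
        low = col.lower()
        if low.endswith(ad_suffix):
            ad_cols[col[: len(col) - len(ad_suffix)]] = col
        elif low.endswith(vote_suffix):
            vote_cols[col[: len(col) - len(vote_suffix)]] = col
    if not vote_cols:
        raise ValueError(
            f"no vote columns found in {path} (expected columns ending in {schema.vote_suffix!r})"
        )
    orphans = set(ad_cols) - set(vote_cols)
    if orphans:
        raise ValueError(f"AD columns without matching vote columns: {sorted(orphans)}")

    model_names = list(vote_cols)
    n, m = len(df), len(model_names)
    votes = np.empty((n, m), dtype=np.int8)
    ad = np.ones((n, m), dtype=bool)
    for j, name in enumerate(model_names):
        col = vote_cols[name]
        votes[:, j] = [normalize_vote(v, row=ids[i], column=col) for i, v in enumerate(df[col])]
        if name in ad_cols:
            acol = ad_cols[name]
            ad[:, j] = [_parse_ad_cell(v, row=ids[i], column=acol) for i, v in enumerate(df[acol])]

    if schema.label_column in df.columns:
        labels = np.array(
            [normalize_label(v, row=ids[i]) for i, v in enumerate(df[schema.label_column])],
            dtype=np.int8,
        )
    else:
        labels = np.full(n, UNKNOWN, dtype=np.int8)

    smiles = [str(s) for s in df[schema.smiles_column]] if schema.smiles_column in df.columns else None

    table = PredictionTable(ids, model_names, votes, ad, labels, smiles)
    n_masked = int((~ad).sum())
    logger.info(
        "read %d chemicals x %d models from %s (%d votes masked out of AD)",
        n, m, path, n_masked,
    )
    return table


def write_prediction_table(table: PredictionTable, path: str | Path,
                           schema: TableSchema | None = None) -> None:
    """Write a prediction table to CSV in the layout `read_prediction_table`
    accepts, preserving all fields (round-trip safe)."""
    schema = schema or TableSchema()
    data: dict[str, list] = {schema.id_column: table.chemical_ids}
    if table.smiles is not None:
        data[schema.smiles_column] = table.smiles
    data[schema.label_column] = [label_to_token(c) for c in table.true_labels]
    for j, name in enumerate(table.model_names):
        data[name + schema.vote_suffix] = [vote_to_token(c) for c in table.votes[:, j]]
        data[name + schema.ad_suffix] = ["true" if f else "false" for f in table.ad_mask[:, j]]
    pd.DataFrame(data).to_csv(path, index=False)


def write_consensus_results(results, path: str | Path) -> None:
    """Serialise a consensus run to CSV.

    Columns: chemical id, fused class (or ``not-predicted`` with an empty
    agreement/posterior left intact), majority agreement fraction, number of
    in-AD votes, and — for Bayes runs — both posterior probabilities at
    >= 6 significant digits so regression tests can compare them.
    """
    data: dict[str, list] = {
        "chemical_id": results.chemical_ids,
        "consensus_class": [
            NOT_PREDICTED_TOKEN if c == NO_PREDICTION else vote_to_token(c)
            for c in results.fused
        ],
        "n_votes": [int(v) for v in results.n_votes],
        "agreement": [f"{a:.6g}" for a in results.agreement],
    }
    if results.posterior_active is not None:
        data["posterior_active"] = [f"{p:.8g}" for p in results.posterior_active]
        data["posterior_inactive"] = [f"{1.0 - p:.8g}" for p in results.posterior_active]
    pd.DataFrame(data).to_csv(path, index=False)
    n_abstain = int(np.sum(results.fused == NO_PREDICTION))
    logger.info("wrote %d consensus rows to %s (%d abstentions)", len(results.chemical_ids), path, n_abstain)


def read_consensus_results(path: str | Path):
    """Read back a consensus CSV written by :func:`write_consensus_results`."""
    from .consensus import ConsensusResult  # local import to avoid a cycle

    df = pd.read_csv(path, dtype={"chemical_id": str}, keep_default_na=False)
    fused = np.array(
        [normalize_vote(v, row=i, column="consensus_class") for i, v in enumerate(df["consensus_class"])],
        dtype=np.int8,
    )
    posterior = None
    if "posterior_active" in df.columns:
        posterior = df["posterior_active"].astype(float).to_numpy()
    return ConsensusResult(
        chemical_ids=[str(x) for x in df["chemical_id"]],
        fused=fused,
        n_votes=df["n_votes"].astype(int).to_numpy(),
        agreement=df["agreement"].astype(float).to_numpy(),
        posterior_active=posterior,
        config=None,
        metadata={"source": str(path)},
    )
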