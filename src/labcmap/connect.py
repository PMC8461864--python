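"""Lab-catalog harmonization and the repurposing possibility score.

The connectivity-map step: a drug's ternary lab signature (+1 up, -1 down,
0 no effect) is matched against a disease's ternary lab signature over a
shared, harmonized lab catalog.  The repurposing possibility score of a
drug-disease pair is the *negative* dot product of the two vectors,

    TS(drug, disease) = - CV_drug . CV_disease,

so labs where the drug opposes the disease (complementary directions)
add +1 and labs where it moves the same way (adverse) add -1.  A positive
score means net complementarity and hence therapeutic potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_ALLOWED = frozenset({-1.0, 0.0, 1.0})


@dataclass(frozen=True)
class LabCatalog:
    """Ordered list of harmonized lab identifiers shared by both sources."""

    labs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labs)) != len(self.labs):
            raise ValueError("lab catalog contains duplicate ids")

    def __len__(self) -> int:
        return len(self.labs)

    def __iter__(self):
        return iter(self.labs)


@dataclass
class SignVector:
    """Ternary lab-effect vector for one drug or one disease.

    ``entries`` is indexed by the shared lab catalog, in catalog order, with
    values in {+1.0, -1.0, 0.0}.
    """

    entity_id: str
    entries: pd.Series

    def __post_init__(self) -> None:
        self.entries = self.entries.astype(float)
        bad = set(self.entries.unique()) - _ALLOWED
        if bad:
            raise ValueError(f"sign vector values must be in {{+1,-1,0}}, got {bad}")
        if self.entries.index.has_duplicates:
            raise ValueError("duplicate lab ids in sign vector")

    @property
    def catalog(self) -> tuple[str, ...]:
        return tuple(self.entries.index)

    def values(self) -> np.ndarray:
        return self.entries.to_numpy(dtype=float)


def harmonize_labs(
    aliases_a: Mapping[str, str], aliases_b: Mapping[str, str]
) -> LabCatalog:
    """Intersect two sources' lab catalogs under their alias maps.

    Each alias map sends a source-specific lab name to a harmonized lab id.
    The shared catalog is the intersection of mapped ids, sorted for
    determinism.  Raises ``ValueError`` when the intersection is empty —
    no scoring is possible without at least one shared lab.
    """
    shared = set(aliases_a.values()) & set(aliases_b.values())
    if not shared:
        raise ValueError("no labs shared between the two sources after aliasing")
    return LabCatalog(labs=tuple(sorted(shared)))


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (source_name, lab_id) CSV alias map."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("alias map needs two columns: source_name, lab_id")
    src, dst = df.columns[:2]
    return dict(zip(df[src].astype(str), df[dst].astype(str)))


def repurposing_score(drug: SignVector, disease: SignVector) -> float:
    """Negative dot product of the two ternary vectors (the TS score)."""
    if drug.catalog != disease.catalog:
        raise ValueError(
            f"catalog mismatch between {drug.entity_id!r} and {disease.entity_id!r}"
        )
    return -float(drug.values() @ disease.values())


def score_matrix(
    drugs: Iterable[SignVector], diseases: Iterable[SignVector]
) -> pd.DataFrame:
    """Drugs x diseases matrix of repurposing possibility scores.

    Rows and columns are sorted by id so the output is deterministic under
    any input ordering.
    """
    drug_list = sorted(drugs, key=lambda v: v.entity_id)
    dz_list = sorted(diseases, key=lambda v: v.entity_id)
    if not drug_list or not dz_list:
        raise ValueError("score_matrix needs at least one drug and one disease")
    data = np.array(
        [[repurposing_score(dr, dz) for dz in dz_list] for dr in drug_list]
    )
    return pd.DataFrame(
        data,
        index=pd.Index([v.entity_id for v in drug_list], name="drug_id"),
        columns=pd.Index([v.entity_id for v in dz_list], name="disease_id"),
    )


def rank_drugs(matrix: pd.DataFrame, disease_id: str) -> list[str]:
    """Drugs in descending score order; ties broken by ascending drug id."""
    if disease_id not in matrix.columns:
        raise KeyError(f"unknown disease {disease_id!r}")
    col = matrix[disease_id]
    order = sorted(col.index, key=lambda d: (-col[d], d))
    return list(order)


def write_rankings(
    matrix: pd.DataFrame, out_dir: str | Path, diseases: Sequence[str] | None = None
) -> None:
    """Write one (rank, drug_id, score) CSV per disease."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for dz in diseases if diseases is not None else matrix.columns:
        ranked = rank_drugs(matrix, dz)
        pd.DataFrame(
            {
                "rank": np.arange(1, len(ranked) + 1),
                "drug_id": ranked,
                "score": [matrix.at[d, dz] for d in ranked],
            }
        ).to_csv(out / f"ranking_{dz}.csv", index=False)
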