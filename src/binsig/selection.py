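"""Per-gene predictive scoring, ranking, signature selection, patient scoring.

The predictive score of a gene counts outcome-concordant extreme expression
across patients: an adverse-outcome (EVENT) patient with HIGH expression, or
a favourable-outcome (NO_EVENT) patient with LOW expression, adds +1; the
discordant combinations add -1; TYPICAL expression contributes nothing.
A gene strongly over-expressed in poor-outcome tumors therefore accumulates a
large positive score and one under-expressed in poor-outcome tumors a large
negative score.  Signatures take the top-n genes by score magnitude, signed
by the score's direction: positive-score genes form the risk set P, negative
the protective set N.  A patient's signature score is
``(sum_P x - sum_N x) / n`` over standardized expression x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import EVENT, EXCLUDED, NO_EVENT, ValidationError


@dataclass(frozen=True)
class GeneSignature:
    """Ordered gene set partitioned into risk (+1) and protective (-1) members."""

    members: tuple  # of (gene_id, sign) pairs, sign in {+1, -1}
    scores: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        genes = [g for g, _ in self.members]
        if len(set(genes)) != len(genes):
            raise ValidationError("signature contains a duplicated gene")
        if any(s not in (1, -1) for _, s in self.members):
            raise ValidationError("signature signs must be +1 or -1")

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def positive(self) -> list[str]:
        """Risk-set genes (high expression tracks the adverse outcome)."""
        return [g for g, s in self.members if s == 1]

    @property
    def negative(self) -> list[str]:
        """Protective-set genes (high expression tracks the favourable outcome)."""
        return [g for g, s in self.members if s == -1]


def predictive_scores(
    bins: pd.DataFrame, z: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Score every gene against the binary phenotype.

    Parameters
    ----------
    bins : DataFrame of codes in {-1, 0, +1} (LOW/TYPICAL/HIGH), genes x samples.
    z : standardized matrix on the same axes (used for the tie-break).
    labels : per-sample EVENT / NO_EVENT / EXCLUDED; EXCLUDED samples are
        ignored.

    Returns
    -------
    DataFrame indexed by gene with integer ``score`` and non-negative real
    ``tiebreak`` = |mean z among EVENT - mean z among NO_EVENT| columns.
    """
    labels = labels.loc[list(bins.columns)]
    ev = labels == EVENT
    ne = labels == NO_EVENT
    if not ev.any() or not ne.any():
        raise ValidationError("need at least one EVENT and one NO_EVENT patient")

    b = bins.to_numpy()
    # LOW/HIGH codes are the per-patient contributions for EVENT patients and
    # their negation for NO_EVENT patients, so the rule table collapses to a
    # signed sum of bin codes.
    score = b[:, ev.to_numpy()].sum(axis=1) - b[:, ne.to_numpy()].sum(axis=1)

    zz = z.loc[bins.index].to_numpy()
    tiebreak = np.abs(
        zz[:, ev.to_numpy()].mean(axis=1) - zz[:, ne.to_numpy()].mean(axis=1)
    )
    return pd.DataFrame(
        {"score": score.astype(int), "tiebreak": tiebreak}, index=bins.index
    )


def rank_genes(table: pd.DataFrame) -> list[str]:
    """Order genes by decreasing score magnitude.

    Ties in |score| fall back to the tie-break magnitude (descending), then
    to lexicographic gene id so runs are reproducible.
    """
    if table.empty:
        raise ValidationError("empty score table")
    ids = table.index.to_numpy()
    abs_score = table["score"].abs().to_numpy(dtype=float)
    tiebreak = table["tiebreak"].to_numpy(dtype=float)
    # lexsort: last key is primary
    order = np.lexsort((ids, -tiebreak, -abs_score))
    return list(ids[order])


def select_signature(table: pd.DataFrame, n: int) -> GeneSignature:
    """Take the n most predictive genes as a signed signature.

    Genes with score 0 carry no direction and are never selectable; ``n``
    must not exceed the number of nonzero-score genes.
    """
    nonzero = int((table["score"] != 0).sum())
    if n < 1:
        raise ValidationError(f"signature length must be >= 1, got {n}")
    if n > nonzero:
        raise ValidationError(
            f"requested {n} genes but only {nonzero} have nonzero score"
        )
    ranked = rank_genes(table)[:n]
    members = tuple(
        (g, 1 if table.at[g, "score"] > 0 else -1) for g in ranked
    )
    scores = {g: int(table.at[g, "score"]) for g in ranked}
    return GeneSignature(members=members, scores=scores)


def score_patients(sig: GeneSignature, z: pd.DataFrame) -> pd.Series:
    """Per-patient signature score ``(sum_P x - sum_N x) / n``.

    ``z`` must be standardized within the cohort being scored.
    """
    missing = [g for g, _ in sig.members if g not in z.index]
    if missing:
        raise ValidationError(f"signature genes missing from matrix: {missing}")
    signs = np.array([s for _, s in sig.members], dtype=float)
    x = z.loc[[g for g, _ in sig.members]].to_numpy()
    return pd.Series(signs @ x / sig.n, index=z.columns, name="signature_score")


def write_signature(sig: GeneSignature, table: pd.DataFrame | None, path) -> None:
    """Serialize a signature as TSV (gene_id, sign, score, tiebreak)."""
    rows = []
    for g, s in sig.members:
        score = sig.scores.get(g, 0)
        tb = float(table.at[g, "tiebreak"]) if table is not None else float("nan")
        rows.append((g, s, score, tb))
    pd.DataFrame(rows, columns=["gene_id", "sign", "score", "tiebreak"]).to_csv(
        path, sep="\t", index=False
    )


def read_signature(path) -> GeneSignature:
    """Read a signature written by :func:`write_signature`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    members = tuple((g, int(s)) for g, s in zip(df["gene_id"], df["sign"]))
    scores = {g: int(sc) for g, sc in zip(df["gene_id"], df["score"])}
    return GeneSignature(members=members, scores=scores)
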