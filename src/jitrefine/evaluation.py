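"""Catalog matching: overlap score and sensitivity/specificity/f-measure.

A predicted complex ``Pc`` matches a known complex ``Kc`` when their
overlap score

    OS(Pc, Kc) = |Pc ∩ Kc|^2 / (|Pc| * |Kc|)

is at least a cutoff (0.2 by convention); OS = 1 iff the sets are equal
(a perfect match).  Counting matches on each side gives MPC (predicted
complexes matching some known complex) and MKC (known complexes matched
by some prediction); from TP = MPC, FP = PC - TP and FN = #known - MKC
follow Sn = TP/(TP+FN), Sp = TP/(TP+FP) and their harmonic mean, the
f-measure.  Note Sn mixes counts of predicted (TP) and known (FN)
complexes; the purely known-side rate MKC/#known is reported alongside
as ``sn_known``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from jitrefine.io import ComplexCatalog


def overlap_score(pred: Iterable[str], known: Iterable[str]) -> float:
    """OS(Pc, Kc) = |Pc ∩ Kc|^2 / (|Pc| * |Kc|); 0 when disjoint, 1 iff equal."""
    pred, known = set(pred), set(known)
    if not pred or not known:
        raise ValueError("overlap score of an empty set is undefined")
    inter = len(pred & known)
    return inter * inter / (len(pred) * len(known))


@dataclass
class MatchReport:
    """Counts and rates from matching a predicted catalog to a known one."""

    pc: int  # number of predicted complexes
    n_known: int
    os_threshold: float
    tp: int  # predicted matching >= 1 known (= MPC)
    fp: int  # predicted matching none
    fn: int  # known matched by none
    mkc: int  # known matched by >= 1 prediction
    mpc: int
    perfect: int  # predicted with OS exactly 1 against some known
    sn: float
    sp: float
    f_measure: float
    sn_known: float  # MKC / n_known, the prose (known-side) sensitivity

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def summary(self) -> str:
        d = self.to_dict()
        lines = [f"{k}\t{v:.4f}" if isinstance(v, float) else f"{k}\t{v}" for k, v in d.items()]
        return "\n".join(lines)


def match_catalogs(
    predicted: ComplexCatalog,
    known: ComplexCatalog,
    os_threshold: float = 0.2,
) -> MatchReport:
    """Match every predicted complex against every known complex.

    A complex may match several on the other side; no one-to-one
    assignment is made.  f-measure is defined as 0 when Sn = Sp = 0.
    """
    if len(predicted) == 0 or len(known) == 0:
        raise ValueError("cannot evaluate an empty catalog")
    pred_best = [max(overlap_score(p, k) for k in known) for p in predicted]
    known_best = [max(overlap_score(p, k) for p in predicted) for k in known]
    tp = sum(1 for s in pred_best if s >= os_threshold)
    mkc = sum(1 for s in known_best if s >= os_threshold)
    perfect = sum(1 for s in pred_best if s == 1.0)
    pc, nk = len(predicted), len(known)
    fp = pc - tp
    fn = nk - mkc
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * sp * sn / (sp + sn) if sp + sn else 0.0
    return MatchReport(
        pc=pc,
        n_known=nk,
        os_threshold=os_threshold,
        tp=tp,
        fp=fp,
        fn=fn,
        mkc=mkc,
        mpc=tp,
        perfect=perfect,
        sn=sn,
        sp=sp,
        f_measure=f,
        sn_known=mkc / nk,
    )


def os_threshold_sweep(
    predicted: ComplexCatalog,
    known: ComplexCatalog,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """MKC and MPC at each OS cutoff; both are non-increasing in the cutoff."""
    if any(not 0.0 < t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    rows = []
    for t in thresholds:
        rep = match_catalogs(predicted, known, os_threshold=t)
        rows.append({"os_threshold": t, "MKC": rep.mkc, "MPC": rep.mpc})
    return pd.DataFrame(rows)
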