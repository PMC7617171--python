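"""Clade-level combination of family posteriors and the results table.

Families are analysed independently, so clade-level statements combine
their posteriors under independence: the probability that a clade
originated before a threshold age (default 66 Ma, the K-Pg boundary) is
one minus the product over member families of the probability that each
family is younger. Lineage-through-time (LTT) curves count families whose
posterior interval bounds bracket each 1-Myr grid point, adding a family
at its origination bound and removing it at its extinction bound (extant
families are never removed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mcmc import FamilyEstimate, Trace
from .strat_ci import StratRecord, ci_extension, extinction_ci, origin_ci

__all__ = [
    "CladeAssignment",
    "LTTCurves",
    "clade_origin_probability",
    "ltt",
    "RESULT_COLUMNS",
    "write_results",
]

KPG_BOUNDARY_MA = 66.0


@dataclass
class CladeAssignment:
    """Clade labels for one family, broadest first, plus stem/crown flag."""

    family: str
    clades: tuple
    stem_or_crown: str = ""

    def __post_init__(self) -> None:
        if not self.clades:
            raise ValueError(f"family {self.family!r} needs at least one clade label")


@dataclass
class LTTCurves:
    """Family richness through time under upper and lower interval bounds."""

    time: np.ndarray
    upper: np.ndarray
    lower: np.ndarray


def clade_origin_probability(
    traces: Mapping[str, Trace] | Sequence[Trace],
    threshold: float = KPG_BOUNDARY_MA,
) -> float:
    """P(at least one member family originated before ``threshold`` Ma).

    Family posteriors are treated as independent (each family is analysed
    separately), so the probability is 1 - prod_f P(root_f <= threshold),
    with each factor estimated as the fraction of that family's posterior
    samples younger than the threshold. Monotone non-decreasing as
    families are added.
    """
    seq = list(traces.values()) if isinstance(traces, Mapping) else list(traces)
    if not seq:
        raise ValueError("need at least one family trace")
    log_p_none = 0.0
    for tr in seq:
        p_younger = float(np.mean(tr.t_origin <= threshold))
        if p_younger == 0.0:
            return 1.0
        log_p_none += np.log(p_younger)
    return float(1.0 - np.exp(log_p_none))


def _bound_pair(est: FamilyEstimate, bound: str) -> tuple[float, float | None]:
    if bound == "upper":
        root = est.root_upper
        ext = est.ext_upper
    elif bound == "lower":
        root = est.root_lower
        ext = est.ext_lower
    else:
        raise ValueError("bound must be 'upper' or 'lower'")
    return root, ext


def ltt(
    estimates: Sequence[FamilyEstimate],
    bin_width: float = 1.0,
) -> LTTCurves:
    """Lineage-through-time curves from family interval bounds.

    ``richness(t)`` counts families with origination bound >= t and (if
    extinct) extinction bound <= t, on a 1-Myr grid from the present to
    the oldest bound.
    """
    if not estimates:
        raise ValueError("no estimates")
    t_max = max(e.root_upper for e in estimates)
    time = np.arange(0.0, np.ceil(t_max) + bin_width, bin_width)
    curves = {}
    for bound in ("upper", "lower"):
        rich = np.zeros_like(time)
        for est in estimates:
            root, ext = _bound_pair(est, bound)
            alive = time <= root
            if ext is not None:
                alive &= time >= ext
            rich += alive
        curves[bound] = rich
    return LTTCurves(time=time, upper=curves["upper"], lower=curves["lower"])


#: Column layout of the per-family results table.
RESULT_COLUMNS = [
    "family",
    "N_extant",
    "N_fossils",
    "oldest_fossil",
    "youngest_fossil",
    "root_est",
    "root_lower",
    "root_upper",
    "ext_est",
    "ext_lower",
    "ext_upper",
    "q_est",
    "q_lower",
    "q_upper",
    "a_est",
    "a_lower",
    "a_upper",
    "sig2_est",
    "sig2_lower",
    "sig2_upper",
    "clades",
    "stem_or_crown",
    "horizons",
    "strat_range",
    "alpha",
    "marsh_origin_lower",
    "marsh_origin_upper",
    "marsh_ext_lower",
    "marsh_ext_upper",
    "min_ess",
    "converged",
]


def write_results(
    estimates: Sequence[FamilyEstimate],
    family_data: Mapping[str, Mapping],
    path,
    clade_assignments: Mapping[str, CladeAssignment] | None = None,
    strat_records: Mapping[str, StratRecord] | None = None,
) -> pd.DataFrame:
    """Assemble and write the per-family results CSV.

    ``family_data`` maps family name to a dict with at least ``n_extant``,
    ``n_fossils``, ``oldest_fossil`` and ``youngest_fossil``. Extinction
    columns are blank for extant families; stratigraphic columns are blank
    when no horizon record is supplied.
    """
    rows = []
    for est in estimates:
        fam = est.family
        if fam not in family_data:
            raise KeyError(f"family {fam!r}: missing family_data entry")
        meta = family_data[fam]
        for key in ("n_extant", "n_fossils", "oldest_fossil", "youngest_fossil"):
            if key not in meta:
                raise KeyError(f"family {fam!r}: missing field {key!r}")
        row = {
            "family": fam,
            "N_extant": meta["n_extant"],
            "N_fossils": meta["n_fossils"],
            "oldest_fossil": meta["oldest_fossil"],
            "youngest_fossil": meta["youngest_fossil"],
            "root_est": est.root_est,
            "root_lower": est.root_lower,
            "root_upper": est.root_upper,
            "ext_est": est.ext_est,
            "ext_lower": est.ext_lower,
            "ext_upper": est.ext_upper,
            "q_est": est.q_est,
            "q_lower": est.q_lower,
            "q_upper": est.q_upper,
            "a_est": est.a_est,
            "a_lower": est.a_lower,
            "a_upper": est.a_upper,
            "sig2_est": est.sig2_est,
            "sig2_lower": est.sig2_lower,
            "sig2_upper": est.sig2_upper,
            "min_ess": est.min_ess,
            "converged": est.converged,
        }
        if clade_assignments and fam in clade_assignments:
            ca = clade_assignments[fam]
            row["clades"] = ";".join(ca.clades)
            row["stem_or_crown"] = ca.stem_or_crown
        else:
            row["clades"] = ""
            row["stem_or_crown"] = ""
        if strat_records and fam in strat_records:
            sr = strat_records[fam]
            row["horizons"] = sr.H
            row["strat_range"] = sr.R
            if sr.H >= 2:
                row["alpha"] = ci_extension(sr.R, sr.H, sr.C)
                row["marsh_origin_lower"], row["marsh_origin_upper"] = origin_ci(sr)
                row["marsh_ext_lower"], row["marsh_ext_upper"] = extinction_ci(sr)
        rows.append(row)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False)
    return df
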