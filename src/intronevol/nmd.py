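"""NMD visibility of retained introns and the 3n-deficiency logistic model.

A transcript that retains an intron is visible to nonsense-mediated decay
if retention shifts the reading frame (intron length not a multiple of 3)
or if the retained sequence carries an in-frame premature termination
codon (PTC).  A 3n, PTC-free intron is invisible: failed splicing then
yields a translatable but corrupted protein.  The logistic model asks
whether 3n introns are more likely to carry a PTC than frame-shifting ones
-- a deficiency of NMD-invisible introns -- and whether that deficiency is
stronger among recently gained (novel) introns than among conserved ones.

The reading frame inside a retained intron starts ``(3 - phase) mod 3``
nucleotides into the intron, which makes the first full codon of a phase-2
intron with a canonical GT(A/G)A donor read T(A/G)A: the Ochre or Opal
stop.  Phase-2 canonical-donor introns therefore always carry a PTC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .io_formats import STOP_CODONS

logger = logging.getLogger(__name__)


def retention_frame_offset(phase: int) -> int:
    """0-based intron position of the first codon lying fully inside the
    intron when it is retained: (3 - phase) mod 3."""
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
    return (3 - phase) % 3


@dataclass(frozen=True)
class NMDAnnotation:
    length: int
    phase: int
    length_mod3: int
    is_3n: bool
    has_ptc: bool
    first_ptc_offset: int | None
    nmd_visible: bool
    boundary_ptc: bool = False
    n_ambiguous_codons: int = 0


def scan_ptc(
    intron_seq: str,
    phase: int,
    flank5: str = "",
    flank3: str = "",
    include_boundary: bool = False,
) -> NMDAnnotation:
    """Scan a retained intron for in-frame stop codons.

    Stops {TAA, TAG, TGA} are sought at intron offsets
    retention_frame_offset(phase), +3, +6, ... for codons lying strictly
    inside the intron.  With ``include_boundary`` the codons spanning the
    exon-intron and intron-exon junctions (built from the flanks) are also
    checked; a stop found only there sets ``has_ptc`` but leaves
    ``first_ptc_offset`` to the first fully internal stop (None if none).
    Codons containing an ambiguous base are skipped and counted.
    """
    seq = intron_seq.upper()
    L = len(seq)
    if L < 1:
        raise ValueError("empty intron sequence")
    off = retention_frame_offset(phase)
    first: int | None = None
    ambiguous = 0
    for i in range(off, L - 2, 3):
        codon = seq[i:i + 3]
        if "N" in codon:
            ambiguous += 1
            continue
        if codon in STOP_CODONS:
            first = i
            break
    boundary_hit = False
    if include_boundary:
        f5, f3 = flank5.upper(), flank3.upper()
        if phase and len(f5) < phase:
            raise ValueError("flank5 shorter than phase; cannot build junction codon")
        whole = f5 + seq + f3
        start0 = (len(f5) - phase) % 3
        for p in range(start0, len(whole) - 2, 3):
            # codons overlapping but not inside the intron
            inside = p >= len(f5) and p + 3 <= len(f5) + L
            overlaps = p + 3 > len(f5) and p < len(f5) + L
            if inside or not overlaps:
                continue
            codon = whole[p:p + 3]
            if len(codon) < 3:
                continue
            if "N" in codon:
                ambiguous += 1
                continue
            if codon in STOP_CODONS:
                boundary_hit = True
                break
    if ambiguous:
        logger.debug("scan_ptc: skipped %d codon(s) with ambiguous bases", ambiguous)
    has_ptc = first is not None or boundary_hit
    is_3n = L % 3 == 0
    return NMDAnnotation(
        length=L,
        phase=phase,
        length_mod3=L % 3,
        is_3n=is_3n,
        has_ptc=has_ptc,
        first_ptc_offset=first,
        nmd_visible=(not is_3n) or has_ptc,
        boundary_ptc=boundary_hit,
        n_ambiguous_codons=ambiguous,
    )


def annotate_introns(df: pd.DataFrame, include_boundary: bool = False) -> pd.DataFrame:
    """Vectorized wrapper: adds NMD columns to a frame with seq and phase."""
    anns = [
        scan_ptc(seq, int(phase), include_boundary=include_boundary)
        for seq, phase in zip(df["seq"], df["phase"])
    ]
    out = df.copy()
    out["length"] = [a.length for a in anns]
    out["is_3n"] = [a.is_3n for a in anns]
    out["has_ptc"] = [a.has_ptc for a in anns]
    out["first_ptc_offset"] = [
        -1 if a.first_ptc_offset is None else a.first_ptc_offset for a in anns
    ]
    out["nmd_visible"] = [a.nmd_visible for a in anns]
    return out


# ---------------------------------------------------------------------------
# logistic model
# ---------------------------------------------------------------------------

CONTRAST_NAMES = ("novel_3n_vs_non3n", "conserved_3n_vs_non3n", "novel_vs_conserved")


@dataclass
class RegressionResult:
    coef_table: pd.DataFrame        # term, estimate, wald_chi2, p
    contrasts: pd.DataFrame         # contrast, odds_ratio, ci_low, ci_high
    pseudo_r2: float                # McFadden
    n_per_cell: dict[str, int]
    standard_fit: bool = True       # False when a penalized fallback was used

    def odds_ratio(self, contrast: str) -> float:
        row = self.contrasts.set_index("contrast").loc[contrast]
        return float(row["odds_ratio"])


def fit_ptc_model(
    table: pd.DataFrame, log_length: bool = False
) -> RegressionResult:
    """Binomial GLM of PTC occurrence on length, phase and group x 3n class.

    ``table`` needs columns: length (bp), phase (0/1/2), group
    ("novel"/"conserved"), has_ptc (bool); is_3n is derived from length if
    absent.  The group x 3n cross is entered as a 4-level factor with
    conserved_non3n as reference, and three odds-ratio contrasts are
    reported: the 3n-vs-non3n effect within novel introns, the same within
    conserved introns, and the ratio of those two (novel vs conserved).
    OR > 1 means 3n introns carry PTCs more often than frame-shifting
    introns of the same group: a deficiency of NMD-invisible introns.
    """
    df = table.copy()
    required = {"length", "phase", "group", "has_ptc"}
    if missing := required - set(df.columns):
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if len(df) < 50:
        raise ValueError("need at least 50 introns to fit the model")
    if "is_3n" not in df.columns:
        df["is_3n"] = df["length"] % 3 == 0
    if set(df["group"]) - {"novel", "conserved"}:
        raise ValueError("group must be 'novel' or 'conserved'")
    df["cell"] = df["group"] + np.where(df["is_3n"], "_3n", "_non3n")
    df["has_ptc"] = df["has_ptc"].astype(int)
    df["len_cov"] = np.log(df["length"]) if log_length else df["length"].astype(float)
    n_per_cell = df["cell"].value_counts().to_dict()
    if df["phase"].nunique() < 2 or df["cell"].nunique() < 4:
        raise ValueError("need >=2 phase levels and all four group x 3n cells")

    formula = "has_ptc ~ len_cov + C(phase) + C(cell, Treatment(reference='conserved_non3n'))"
    model = smf.glm(formula, data=df, family=sm.families.Binomial())
    standard = True
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit()
        if not res.converged or np.any(~np.isfinite(res.bse)):
            raise PerfectSeparationError("non-finite standard errors")
    except (
        PerfectSeparationError,
        PerfectSeparationWarning,
        np.linalg.LinAlgError,
    ) as exc:
        logger.warning("standard GLM fit failed (%s); penalized fallback", exc)
        standard = False
        res = model.fit_regularized(alpha=1.0 / len(df), L1_wt=0.0)

    params = pd.Series(res.params, index=model.exog_names)
    prefix = "C(cell, Treatment(reference='conserved_non3n'))"
    term = lambda cell: f"{prefix}[T.{cell}]"

    def contrast_vector(weights: dict[str, float]) -> np.ndarray:
        v = np.zeros(len(params))
        for name, w in weights.items():
            v[list(params.index).index(name)] = w
        return v

    vectors = {
        "novel_3n_vs_non3n": contrast_vector(
            {term("novel_3n"): 1.0, term("novel_non3n"): -1.0}
        ),
        "conserved_3n_vs_non3n": contrast_vector({term("conserved_3n"): 1.0}),
    }
    vectors["novel_vs_conserved"] = (
        vectors["novel_3n_vs_non3n"] - vectors["conserved_3n_vs_non3n"]
    )

    if standard:
        cov = np.asarray(res.cov_params())
        bse = pd.Series(res.bse, index=model.exog_names)
        wald_chi2 = (params / bse) ** 2
        from scipy import stats as sps

        pvals = sps.chi2.sf(wald_chi2, df=1)
        coef_table = pd.DataFrame(
            {
                "term": params.index,
                "estimate": params.to_numpy(),
                "wald_chi2": wald_chi2.to_numpy(),
                "p": pvals,
            }
        )
        null = smf.glm("has_ptc ~ 1", data=df, family=sm.families.Binomial()).fit()
        pseudo_r2 = 1.0 - res.llf / null.llf
    else:
        cov = None
        coef_table = pd.DataFrame(
            {
                "term": params.index,
                "estimate": params.to_numpy(),
                "wald_chi2": np.nan,
                "p": np.nan,
            }
        )
        pseudo_r2 = float("nan")

    rows = []
    for name in CONTRAST_NAMES:
        v = vectors[name]
        est = float(v @ params.to_numpy())
        if cov is not None:
            se = float(np.sqrt(v @ cov @ v))
            lo, hi = est - 1.959963984540054 * se, est + 1.959963984540054 * se
        else:
            lo = hi = float("nan")
        rows.append(
            {
                "contrast": name,
                "odds_ratio": float(np.exp(est)),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
            }
        )
    contrasts = pd.DataFrame(rows)
    return RegressionResult(
        coef_table=coef_table,
        contrasts=contrasts,
        pseudo_r2=float(pseudo_r2),
        n_per_cell=n_per_cell,
        standard_fit=standard,
    )


def phase_stop_constraint_report(table: pd.DataFrame) -> pd.DataFrame:
    """PTC fraction by phase, plus the canonical-donor phase-2 fraction.

    For phase-2 introns whose donor is GT(A/G)AGT the first internal codon
    is T(A/G)A, a stop, so their PTC fraction is 1 by construction; the
    report makes that constraint visible next to the other phases.
    Expects columns phase, donor6, has_ptc.
    """
    from .splice import donor_is_consensus

    rows = []
    for phase in (0, 1, 2):
        sub = table[table["phase"] == phase]
        rows.append(
            {
                "phase": phase,
                "n": len(sub),
                "ptc_fraction": float(sub["has_ptc"].mean()) if len(sub) else float("nan"),
            }
        )
    canon2 = table[
        (table["phase"] == 2) & table["donor6"].map(donor_is_consensus)
    ]
    rows.append(
        {
            "phase": "2_canonical_donor",
            "n": len(canon2),
            "ptc_fraction": float(canon2["has_ptc"].mean()) if len(canon2) else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def phase2_canonical_ptc_fraction(table: pd.DataFrame) -> float:
    rep = phase_stop_constraint_report(table).set_index("phase")
    return float(rep.loc["2_canonical_donor", "ptc_fraction"])
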