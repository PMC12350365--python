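"""Genotype call encoding, locus filtering, and locus subsampling.

Call strings such as "0/0" or "1/2" are mapped to additive dosage codes
{0, 0.5, 1, 0.15}: homozygous reference 0, heterozygous ref/alt 0.5,
homozygous alternate 1, and any other (multi-allelic) call the sentinel
0.15. Loci with missing calls are dropped, then an informative-locus rule
keeps loci that segregate (enough heterozygotes, not dominated by zeros, no
multi-allelic sentinel), and a fixed-size random subset feeds the models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LocusFilterParams

#: Dosage codes for the four standard diploid biallelic calls.
CALL_CODES = {"0/0": 0.0, "0/1": 0.5, "1/0": 0.5, "1/1": 1.0}
#: Sentinel dosage for any other non-missing call ("2/0", "2/2", ...).
OTHER_CODE = 0.15
#: The closed set of valid encoded values.
VALID_CODES = frozenset({0.0, 0.15, 0.5, 1.0})


@dataclass
class LocusFilterReport:
    """Bookkeeping from a locus-dropping pass."""

    removed: list[str]
    missing_fraction: dict[str, float]


def encode_calls(
    calls: pd.DataFrame,
    missing_marker: str = "./.",
) -> pd.DataFrame:
    """Encode a hybrids x loci table of call strings to dosages.

    Missing markers (and NaN) stay missing. Numeric inputs already in the
    code set pass through unchanged; numeric values outside it raise, since
    silent re-encoding of an unknown numeric code would corrupt the matrix.
    """
    table = calls.set_index("Hybrid") if "Hybrid" in calls.columns else calls

    def encode_cell(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, (int, float, np.integer, np.floating)):
            if float(v) in VALID_CODES:
                return float(v)
            raise ValueError(f"numeric genotype value outside code set: {v!r}")
        s = str(v).strip()
        if s == missing_marker or s in {".", "", "nan"}:
            return np.nan
        return CALL_CODES.get(s, OTHER_CODE)

    return table.map(encode_cell).astype(float)


def drop_missing_loci(
    g: pd.DataFrame,
    policy: str = "any-missing",
    max_missing_fraction: float = 0.8,
) -> tuple[pd.DataFrame, LocusFilterReport]:
    """Remove loci with missing dosages.

    policy "any-missing" removes a locus containing a single missing entry;
    policy "fraction" removes loci whose missing fraction exceeds
    ``max_missing_fraction``.
    """
    frac = g.isna().mean(axis=0)
    if policy == "any-missing":
        removed = list(frac.index[frac > 0])
    elif policy == "fraction":
        removed = list(frac.index[frac > max_missing_fraction])
    else:
        raise ValueError(f"unknown policy: {policy!r}")
    kept = g.drop(columns=removed)
    if kept.shape[1] == 0:
        raise ValueError(
            "all loci removed by the missing-value filter; "
            "consider policy='fraction' with a higher threshold"
        )
    report = LocusFilterReport(removed=removed, missing_fraction={c: float(frac[c]) for c in removed})
    return kept, report


def select_informative_loci(g: pd.DataFrame, p: LocusFilterParams | None = None) -> list[str]:
    """Keep loci that carry contrast across hybrids.

    A locus of H hybrids survives iff its zero-dosage count is strictly below
    ``max_zero_fraction * H``, its heterozygote (0.5) count is at least
    ``min_het_fraction * H``, and (by default) it contains no 0.15 sentinel.
    Input order is preserved. Returns a possibly empty list.
    """
    p = p or LocusFilterParams()
    if g.isna().any().any():
        raise ValueError("select_informative_loci requires a complete (no-missing) matrix")
    h = g.shape[0]
    arr = g.to_numpy(dtype=float)
    n_zero = (arr == 0.0).sum(axis=0)
    n_het = (arr == 0.5).sum(axis=0)
    n_other = (arr == OTHER_CODE).sum(axis=0)
    keep = (n_zero < p.max_zero_fraction * h) & (n_het >= p.min_het_fraction * h)
    if p.forbid_other_code:
        keep &= n_other == 0
    return [c for c, k in zip(g.columns, keep) if k]


def sample_loci(kept: list[str], n_sample: int = 300, seed: int = 0) -> list[str]:
    """Uniform sample without replacement of min(n_sample, len(kept)) loci."""
    if not kept:
        raise ValueError("no loci to sample from")
    if n_sample >= len(kept):
        return list(kept)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(kept), size=n_sample, replace=False)
    return [kept[i] for i in sorted(idx)]


def prepare_genotypes(
    calls: pd.DataFrame,
    params: LocusFilterParams | None = None,
    missing_marker: str = "./.",
) -> tuple[pd.DataFrame, dict]:
    """Full genotype pipeline: encode, drop missing loci, filter, subsample.

    Returns the final dosage matrix restricted to the sampled loci, plus a
    report of counts at each stage.
    """
    params = params or LocusFilterParams()
    encoded = encode_calls(calls, missing_marker=missing_marker)
    complete, drop_report = drop_missing_loci(encoded)
    informative = select_informative_loci(complete, params)
    if informative:
        chosen = sample_loci(informative, params.n_sample, params.seed)
    else:
        # degenerate cohort: fall back to all complete loci so models still run
        chosen = sample_loci(list(complete.columns), params.n_sample, params.seed)
    report = {
        "n_input_loci": encoded.shape[1],
        "n_after_missing_drop": complete.shape[1],
        "n_informative": len(informative),
        "n_sampled": len(chosen),
        "dropped_missing": drop_report.removed,
    }
    return complete[chosen], report
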