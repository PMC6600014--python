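"""Regulatory-feature enrichment and 3' UTR characterisation.

Covers set enrichment of operon membership, spliced-leader classes and
conserved miRNA-family targets (Fisher's exact test against the
quantifiable-gene background, TargetScan targets pre-filtered to
P_ct > 0.8); PWM motif scanning and a length-normalised affinity test
against a log-normal background null; 3' UTR length / GC / folding-energy
summaries; and per-spliced-leader-class translation summaries.

The folding-energy score is an internal nested-structure dynamic
programme (pair energies GC = -3, AU = -2, GU = -1 arbitrary units,
hairpin loops >= 3 unpaired bases) — a deliberately simple stand-in for a
full thermodynamic folder, adequate for comparing sequence sets; callers
may supply externally computed minimum-free-energy values instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import TestResult, fisher_exact_2x2, wilcoxon_rank_sum

__all__ = [
    "PWM",
    "fisher_feature_enrichment",
    "pwm_scan",
    "motif_enrichment",
    "utr_feature_table",
    "mfe_proxy",
    "sl_translation_summary",
]

MIN_UTR_LEN = 12
PCT_MIN = 0.8

_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
_MIN_LOOP = 3
_ALPHABET = "ACGU"


@dataclass
class PWM:
    """Position probability matrix over ACGU with a scanning pseudocount."""

    motif_id: str
    rbp: str
    matrix: np.ndarray  # L x 4, rows sum to 1
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be L x 4 (ACGU)")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each position's probabilities must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]


def _encode_rna(sequence: str) -> np.ndarray:
    seq = sequence.upper().replace("T", "U")
    lut = {b: i for i, b in enumerate(_ALPHABET)}
    try:
        return np.array([lut[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}") from None


def fisher_feature_enrichment(
    target_genes,
    feature_members,
    background_genes,
    mirna_pct: pd.DataFrame | None = None,
    pct_min: float = PCT_MIN,
) -> tuple[TestResult, dict]:
    """Fisher's exact test of feature membership: targets vs background.

    Builds the 2x2 table (target/non-target x member/non-member) over the
    background universe.  In miRNA mode (``mirna_pct`` given, columns gene
    and pct), membership is restricted to conserved targets with
    P_ct > ``pct_min``.  Returns the test and both proportions.
    """
    target = set(target_genes)
    background = set(background_genes)
    if not target <= background:
        raise ValueError("target genes must be a subset of the background")
    members = set(feature_members)
    if mirna_pct is not None:
        conserved = set(mirna_pct.loc[mirna_pct["pct"] > pct_min, "gene"])
        members = members & conserved
    members &= background

    t_in = len(target & members)
    t_out = len(target) - t_in
    rest = background - target
    b_in = len(rest & members)
    b_out = len(rest) - b_in
    res = fisher_exact_2x2([[t_in, t_out], [b_in, b_out]])
    props = {
        "target_proportion": t_in / len(target) if target else np.nan,
        "background_proportion": len(background & members) / len(background),
        "table": [[t_in, t_out], [b_in, b_out]],
    }
    return res, props


def pwm_scan(sequence: str, pwm: PWM) -> tuple[float, np.ndarray]:
    """Log-odds scan of a PWM along the sense strand.

    Scores each start position as sum of log2((p + pc) / 0.25) over the
    motif window; returns (max score, per-position scores).
    """
    enc = _encode_rna(sequence)
    L = len(pwm)
    if enc.size < L:
        raise ValueError("sequence shorter than motif")
    logodds = np.log2((pwm.matrix + pwm.pseudocount) / (0.25 + pwm.pseudocount))
    n_pos = enc.size - L + 1
    idx = np.arange(L)[None, :] + np.arange(n_pos)[:, None]
    scores = logodds[np.arange(L)[None, :], enc[idx]].sum(axis=1)
    return float(scores.max()), scores


def _affinity(sequence: str, pwm: PWM) -> float:
    """Length-normalised affinity: mean of 2**score over start positions."""
    _, scores = pwm_scan(sequence, pwm)
    return float(np.mean(2.0**scores))


def motif_enrichment(
    target_utrs: dict,
    background_utrs: dict,
    pwm: PWM,
    min_len: int = MIN_UTR_LEN,
) -> TestResult:
    """Group motif-affinity test against a log-normal background null.

    Per-sequence affinities (length-normalised mean exponentiated
    log-odds) are computed for the background universe and a log-normal
    null for the *mean* affinity of n target sequences is obtained by
    moment matching; the reported p is the upper-tail probability of the
    observed target-group mean.  UTRs shorter than ``min_len`` are
    excluded from both sets.
    """
    from scipy import stats as sps

    tgt = {g: s for g, s in target_utrs.items() if len(s) >= max(min_len, len(pwm))}
    bg = {g: s for g, s in background_utrs.items() if len(s) >= max(min_len, len(pwm))}
    if not tgt:
        raise ValueError("no usable target sequences")
    if len(bg) < 10:
        raise ValueError("background universe too small")
    bg_aff = np.array([_affinity(s, pwm) for s in bg.values()])
    tgt_aff = np.array([_affinity(s, pwm) for s in tgt.values()])

    n = tgt_aff.size
    m, v = bg_aff.mean(), bg_aff.var(ddof=1)
    v_mean = v / n
    # moment-matched log-normal for the mean of n background affinities
    sigma2 = np.log1p(v_mean / m**2)
    mu = np.log(m) - 0.5 * sigma2
    obs = tgt_aff.mean()
    p = sps.lognorm.sf(obs, s=np.sqrt(sigma2), scale=np.exp(mu))
    return TestResult(
        statistic=float(np.log2(obs / m)),
        p_value=float(min(max(p, 0.0), 1.0)),
        method="pwm_lognormal_group",
        estimate=float(obs / m),
    )


def mfe_proxy(sequence: str) -> float:
    """Minimum folding-energy score over nested structures (DP).

    Pair energies GC = -3, AU = -2, GU = -1; hairpin loops need >= 3
    unpaired bases.  Returns 0 for unfoldable sequences.  T is read as U.
    """
    enc = _encode_rna(sequence)
    n = enc.size
    if n == 0:
        raise ValueError("empty sequence")
    pair_e = np.full((4, 4), np.inf)
    for (a, b), e in _PAIR_ENERGY.items():
        pair_e[_ALPHABET.index(a), _ALPHABET.index(b)] = e

    E = np.zeros((n + 1, n + 1))  # E[i][j] over half-open s[i:j]
    # iterate over span lengths; for each span evaluate every bifurcation
    # k (pairing with the last base) in one matrix operation over (i, k)
    for span in range(_MIN_LOOP + 2, n + 1):
        i_arr = np.arange(0, n - span + 1)
        j_arr = i_arr + span
        best = E[i_arr, j_arr - 1]  # j-1 unpaired
        off = np.arange(0, span - _MIN_LOOP - 1)
        k = i_arr[:, None] + off[None, :]
        cand = (
            E[i_arr[:, None], k]
            + E[k + 1, (j_arr - 1)[:, None]]
            + pair_e[enc[k], enc[j_arr - 1][:, None]]
        )
        E[i_arr, j_arr] = np.minimum(best, cand.min(axis=1))
    return float(E[0, n])


def utr_feature_table(
    utr_seqs: dict,
    gene_sets: dict,
    all_key: str = "all",
    mfe_values: dict | None = None,
    min_len: int = MIN_UTR_LEN,
) -> pd.DataFrame:
    """Per-set mean/SD of UTR length, GC fraction and folding energy.

    ``gene_sets`` maps set name -> gene list and must contain ``all_key``
    (the comparison universe).  Each other set is compared with the
    universe per property by the rank-sum test.  ``mfe_values`` may supply
    externally computed energies keyed by gene; otherwise
    :func:`mfe_proxy` is used.
    """
    if all_key not in gene_sets:
        raise ValueError(f"gene_sets must contain the universe key {all_key!r}")
    usable = {g: s for g, s in utr_seqs.items() if len(s) >= min_len}

    def props(genes):
        seqs = {g: usable[g] for g in genes if g in usable}
        length = np.array([len(s) for s in seqs.values()], dtype=float)
        gc = np.array(
            [(s.upper().count("G") + s.upper().count("C")) / len(s) for s in seqs.values()]
        )
        if mfe_values is not None:
            mfe = np.array([mfe_values[g] for g in seqs])
        else:
            mfe = np.array([mfe_proxy(s) for s in seqs.values()])
        return length, gc, mfe

    ref = props(gene_sets[all_key])
    rows = []
    for name, genes in gene_sets.items():
        length, gc, mfe = props(genes) if name != all_key else ref
        row = {
            "set": name,
            "n": length.size,
            "mean_length": length.mean(),
            "sd_length": length.std(ddof=1),
            "mean_gc": gc.mean(),
            "sd_gc": gc.std(ddof=1),
            "mean_mfe": mfe.mean(),
            "sd_mfe": mfe.std(ddof=1),
        }
        if name != all_key:
            for prop, vals, refvals in (
                ("length", length, ref[0]),
                ("gc", gc, ref[1]),
                ("mfe", mfe, ref[2]),
            ):
                try:
                    row[f"p_{prop}"] = wilcoxon_rank_sum(vals, refvals).p_value
                except ValueError:
                    row[f"p_{prop}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")


def sl_translation_summary(
    annotation_genes: pd.DataFrame,
    translation_logfc: dict,
) -> dict:
    """Mean translation-state log2FC per spliced-leader class per diet.

    ``translation_logfc`` maps diet -> per-gene TR-vs-TO log2FC Series.
    Emits per-class/diet means, pairwise class comparisons within diet and
    AL-vs-DR comparisons within class (rank-sum tests).
    """
    classes = annotation_genes["sl_class"]
    known = {"SL1", "SL2", "native"}
    bad = set(classes.unique()) - known
    if bad:
        raise ValueError(f"unknown SL class labels: {bad}")

    means, tests = {}, {}
    for diet, lfc in translation_logfc.items():
        lfc = lfc.dropna()
        for cls in sorted(known):
            genes = classes.index[classes == cls].intersection(lfc.index)
            means[(diet, cls)] = float(lfc[genes].mean()) if len(genes) else np.nan
        pairs = [("SL1", "native"), ("SL2", "native"), ("SL1", "SL2")]
        for a, b in pairs:
            ga = classes.index[classes == a].intersection(lfc.index)
            gb = classes.index[classes == b].intersection(lfc.index)
            if len(ga) and len(gb):
                tests[(diet, f"{a}_vs_{b}")] = wilcoxon_rank_sum(lfc[ga].values, lfc[gb].values)
    diets = list(translation_logfc)
    if len(diets) == 2:
        a, b = diets
        for cls in sorted(known):
            genes = classes.index[classes == cls]
            ga = genes.intersection(translation_logfc[a].dropna().index)
            gb = genes.intersection(translation_logfc[b].dropna().index)
            if len(ga) and len(gb):
                tests[(f"{a}_vs_{b}", cls)] = wilcoxon_rank_sum(
                    translation_logfc[a][ga].values, translation_logfc[b][gb].values
                )
    return {"means": pd.Series(means), "tests": tests}
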