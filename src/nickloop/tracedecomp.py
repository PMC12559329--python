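"""Simulated-reference Sanger-trace indel decomposition.

A chromatogram is modelled as one scan per called base with four channel
intensities (A, C, G, T): the mixture-weighted base indicator scaled by an
exponential amplitude decay, plus Gaussian noise clipped at zero.  Because
the noiseless model is exactly linear in the mixture fractions, a mutant
trace can be decomposed over a family of *simulated references* — traces
fabricated by inserting or removing bases in the control sequence at the
target site — by non-negative least squares (NNLS).

Standard errors come from the variance-covariance matrix of the
unconstrained normal equations restricted to the NNLS active set, with
``df = n_observations - n_active``; each component gets a two-tailed
t-test.  This quantifies, e.g., the fraction of molecules carrying a
(CTG)4 insertion (repeat expansion) or having lost a (CAG)4 loop (repeat
contraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from nickloop.errors import ConfigError, DegenerateTemplatesError

CHANNELS = "ACGT"
_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNELS)}

DEFAULT_DECAY_RATE = 0.001  # per base; gentle signal loss along the read
DEFAULT_NOISE_SD = 0.01  # as a fraction of the initial peak amplitude
DEFAULT_ALPHA = 0.001


@dataclass
class Chromatogram:
    """Per-scan four-channel trace with base calls (one scan per base)."""

    scans: np.ndarray  # (n_scans, 4), channels A,C,G,T
    called_sequence: str
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.scans = np.asarray(self.scans, dtype=float)
        if self.scans.ndim != 2 or self.scans.shape[1] != 4:
            raise ConfigError("scans must be an (n, 4) array")
        if len(self.called_sequence) != self.scans.shape[0]:
            raise ConfigError("called_sequence length must equal the number of scans")
        if np.any(self.scans < 0):
            raise ConfigError("channel intensities must be >= 0")

    @property
    def n_scans(self) -> int:
        return self.scans.shape[0]


def _indicator(sequence: str, n_scans: int) -> np.ndarray:
    """(n_scans, 4) base-indicator matrix; scans past the sequence end are 0."""
    mat = np.zeros((n_scans, 4))
    for t, base in enumerate(sequence[:n_scans]):
        mat[t, _CHANNEL_INDEX[base]] = 1.0
    return mat


def _amplitude(n_scans: int, decay_rate: float) -> np.ndarray:
    return np.exp(-decay_rate * np.arange(n_scans))


def noiseless_channels(sequence: str, decay_rate: float = DEFAULT_DECAY_RATE,
                       n_scans: Optional[int] = None) -> np.ndarray:
    """Noise-free channel matrix of a single sequence."""
    n = len(sequence) if n_scans is None else n_scans
    return _indicator(sequence, n) * _amplitude(n, decay_rate)[:, None]


def simulate_trace(mixture: Sequence[Tuple[str, float]],
                   decay_rate: float = DEFAULT_DECAY_RATE,
                   noise_sd: float = 0.0,
                   seed: int = 0) -> Chromatogram:
    """Synthesize a chromatogram from a mixture of sequences.

    Scan ``t`` channel ``b`` carries
    ``exp(-decay_rate * t) * sum_k fraction_k * [sequence_k[t] == b]``
    plus N(0, ``noise_sd``) noise (``noise_sd`` is a fraction of the initial
    amplitude), clipped at zero.  Fractions must be non-negative and sum to
    one; base calls are the argmax channel per scan.
    """
    if not mixture:
        raise ConfigError("mixture must contain at least one sequence")
    fracs = np.array([f for _, f in mixture], dtype=float)
    if np.any(fracs < 0):
        raise ConfigError("mixture fractions must be >= 0")
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ConfigError(f"mixture fractions must sum to 1, got {fracs.sum()!r}")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    n_scans = max(len(seq) for seq, _ in mixture)
    scans = np.zeros((n_scans, 4))
    for seq, frac in mixture:
        scans += frac * _indicator(seq, n_scans)
    scans *= _amplitude(n_scans, decay_rate)[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scans = scans + rng.normal(0.0, noise_sd, size=scans.shape)
    scans = np.clip(scans, 0.0, None)
    called = "".join(CHANNELS[i] for i in np.argmax(scans, axis=1))
    return Chromatogram(scans, called,
                        meta={"decay_rate": decay_rate, "noise_sd": noise_sd, "seed": seed})


def write_chromatogram_tsv(chrom: Chromatogram, path) -> None:
    df = pd.DataFrame(chrom.scans, columns=list(CHANNELS))
    df.insert(0, "scan_index", np.arange(chrom.n_scans))
    df["called_base"] = list(chrom.called_sequence)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_chromatogram_tsv(path) -> Chromatogram:
    df = pd.read_csv(path, sep="\t")
    missing = {"scan_index", *CHANNELS, "called_base"} - set(df.columns)
    if missing:
        raise ConfigError(f"chromatogram TSV missing columns: {sorted(missing)}")
    df = df.sort_values("scan_index")
    scans = df[list(CHANNELS)].to_numpy(dtype=float)
    called = "".join(df["called_base"].astype(str))
    return Chromatogram(scans, called)


def apply_indel(sequence: str, size: int, target_site: int,
                inserted_bases: Optional[str] = None) -> str:
    """Insert (``size`` > 0) or delete (``size`` < 0) bases at ``target_site``."""
    if not 0 <= target_site <= len(sequence):
        raise ConfigError(f"target_site {target_site} outside sequence")
    if size > 0:
        if inserted_bases is None or len(inserted_bases) != size:
            raise ConfigError("insertion requires inserted_bases of matching length")
        return sequence[:target_site] + inserted_bases + sequence[target_site:]
    if size < 0:
        if target_site - size > len(sequence):
            raise ConfigError("deletion runs past the sequence end")
        return sequence[:target_site] + sequence[target_site - size:]
    return sequence


def build_simulated_reference(control_sequence: str, size: int, target_site: int,
                              inserted_bases: Optional[str] = None,
                              decay_rate: float = DEFAULT_DECAY_RATE,
                              max_indel: int = 50):
    """Fabricate a reference for one indel by editing the control sequence.

    Returns ``(modified_sequence, noiseless_trace)``; the trace is the
    control's peak pattern with peaks inserted or removed at the target
    site, the way decomposition tools simulate references when no mutant-free
    chromatogram exists.
    """
    if abs(size) > max_indel:
        raise ConfigError(f"|indel size| exceeds the configured maximum {max_indel}")
    seq = apply_indel(control_sequence, size, target_site, inserted_bases)
    return seq, simulate_trace([(seq, 1.0)], decay_rate=decay_rate)


def _phased_insert(expected_insert_bases: str, size: int) -> str:
    """First ``size`` bases of the repeat-unit phased expected insert."""
    reps = size // len(expected_insert_bases) + 1
    return (expected_insert_bases * reps)[:size]


@dataclass
class TemplateSet:
    """Per-shift noiseless reference traces over the fitting window."""

    control_sequence: str
    target_site: int
    shifts: List[int]
    window: Tuple[int, int]
    matrices: Dict[int, np.ndarray] = field(repr=False)
    sequences: Dict[int, str] = field(repr=False)
    decay_rate: float = DEFAULT_DECAY_RATE

    @property
    def n_templates(self) -> int:
        return len(self.shifts)

    def design_matrix(self) -> np.ndarray:
        """Observation matrix: one flattened window trace per shift column."""
        return np.column_stack([self.matrices[s].ravel() for s in self.shifts])

    def inserted_bases(self, shift: int) -> str:
        """Bases inserted for a positive shift (empty for s <= 0)."""
        if shift <= 0:
            return ""
        seq = self.sequences[shift]
        return seq[self.target_site:self.target_site + shift]


def build_templates(control_sequence: str, target_site: int,
                    shift_range: Union[Tuple[int, int], Sequence[int]] = (-15, 15),
                    window: Optional[Tuple[int, int]] = None,
                    expected_insert_bases: str = "CTG",
                    decay_rate: float = DEFAULT_DECAY_RATE,
                    window_span: int = 80) -> TemplateSet:
    """Build the simulated-reference template family for decomposition.

    ``shift_range`` is either ``(min_shift, max_shift)`` or an explicit list
    of shifts (0 is always included).  Positive shifts insert
    ``expected_insert_bases`` phased in repeat units; negative shifts delete
    from the control at the target site.  The default fitting window starts
    5 scans downstream of ``target_site + max(shift)`` and spans
    ``window_span`` scans.
    """
    if len(shift_range) == 2 and not isinstance(shift_range, (list, set)) \
            and shift_range[0] <= 0 <= shift_range[1] and shift_range[0] != shift_range[1]:
        shifts = list(range(int(shift_range[0]), int(shift_range[1]) + 1))
    else:
        shifts = sorted(set(int(s) for s in shift_range) | {0})
    max_del = -min(shifts)
    if target_site + max_del > len(control_sequence):
        raise ConfigError("largest deletion runs past the control sequence end")
    if window is None:
        start = target_site + max(max(shifts), 0) + 5
        window = (start, start + window_span)
    w0, w1 = int(window[0]), int(window[1])
    shortest = len(control_sequence) + min(shifts)
    if not 0 <= w0 < w1 <= shortest:
        raise ConfigError(
            f"window {window} must lie within every shifted sequence (max end {shortest})")

    matrices, sequences = {}, {}
    for s in shifts:
        ins = _phased_insert(expected_insert_bases, s) if s > 0 else None
        seq = apply_indel(control_sequence, s, target_site, ins)
        sequences[s] = seq
        full = noiseless_channels(seq, decay_rate)
        matrices[s] = full[w0:w1]
    return TemplateSet(control_sequence, target_site, shifts, (w0, w1),
                       matrices, sequences, decay_rate)


@dataclass
class DecompositionResult:
    """Per-shift mixture fractions with covariance-based significance."""

    shifts: List[int]
    coefficients: np.ndarray  # raw NNLS coefficients
    fractions: np.ndarray  # coefficients normalized to their sum
    standard_errors: np.ndarray  # NaN for inactive components
    t_statistics: np.ndarray
    p_values: np.ndarray  # 1.0 for inactive components
    r_squared: float
    df: int
    alpha: float
    templates: Optional[TemplateSet] = field(default=None, repr=False)

    @property
    def significant_shifts(self) -> List[int]:
        """Non-zero shifts with p < alpha."""
        return [s for s, p in zip(self.shifts, self.p_values)
                if s != 0 and p < self.alpha]

    def fraction(self, shift: int) -> float:
        return float(self.fractions[self.shifts.index(shift)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "shift": self.shifts,
            "coefficient": self.coefficients,
            "fraction": self.fractions,
            "se": self.standard_errors,
            "t": self.t_statistics,
            "p": self.p_values,
            "significant": [s in self.significant_shifts for s in self.shifts],
        })

    def to_json(self, path) -> None:
        payload = {
            "r_squared": self.r_squared,
            "df": self.df,
            "alpha": self.alpha,
            "components": self.to_frame().replace({np.nan: None}).to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _nnls_tests(y: np.ndarray, X: np.ndarray, shifts_for_error) -> tuple:
    """NNLS fit with active-set covariance t-tests.

    Returns ``(coef, se, t, p, rss, df)`` over the columns of ``X``; inactive
    columns get se = NaN, t = 0, p = 1.
    """
    coef, rnorm = optimize.nnls(X, y)
    rss = float(rnorm ** 2)
    active = np.nonzero(coef > 0)[0]
    df = y.size - active.size
    se = np.full(X.shape[1], np.nan)
    tstat = np.zeros(X.shape[1])
    pval = np.ones(X.shape[1])
    if active.size:
        Xa = X[:, active]
        gram = Xa.T @ Xa
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e12:
            raise DegenerateTemplatesError([shifts_for_error[i] for i in active
                                            if i < len(shifts_for_error)])
        sigma2 = rss / df if df > 0 else 0.0
        cov = sigma2 * np.linalg.inv(gram)
        se_active = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se[active] = se_active
        with np.errstate(divide="ignore", invalid="ignore"):
            t_active = np.where(se_active > 0, coef[active] / se_active, np.inf)
        tstat[active] = t_active
        if df > 0:
            p_active = 2.0 * stats.t.sf(np.abs(t_active), df)
        else:
            p_active = np.zeros_like(t_active)
        pval[active] = np.where(np.isinf(t_active), 0.0, p_active)
    return coef, se, tstat, pval, rss, df


def decompose(mutant: Chromatogram, templates: TemplateSet,
              alpha: float = DEFAULT_ALPHA,
              bonferroni: bool = False,
              baseline: bool = True,
              refit: bool = True) -> DecompositionResult:
    """NNLS decomposition of a mutant trace over the template family.

    The window channels are flattened to one observation vector; NNLS gives
    non-negative per-shift coefficients.  Standard errors derive from the
    variance-covariance matrix ``sigma^2 (X_S' X_S)^-1`` of the unconstrained
    least-squares problem restricted to the active set S, with
    ``df = n_obs - |S|``; each active component gets a two-tailed t-test and
    fractions are the coefficients normalized to their sum.

    Two refinements (on by default) stabilize the estimate against the
    instrument noise floor:

    * ``baseline`` adds a constant regressor absorbing the zero-clipped
      noise floor of real and simulated traces; its coefficient is excluded
      from the fractions.
    * ``refit`` re-runs the fit restricted to the components the first pass
      found significant at ``alpha``.  Without it, the many small spurious
      non-negative coefficients inflate the fraction denominator and bias
      every reported fraction downward by O(noise).

    ``bonferroni`` multiplies p-values by the number of non-control shifts,
    controlling the familywise error of "any spurious indel" at ``alpha``
    (per-component tests alone only control the per-shift error rate).
    """
    w0, w1 = templates.window
    if mutant.n_scans < w1:
        raise ConfigError(
            f"mutant trace ({mutant.n_scans} scans) does not cover the window end {w1}")
    y = mutant.scans[w0:w1].ravel()
    X_all = templates.design_matrix()
    n_shift = X_all.shape[1]

    def _design(cols):
        X = X_all[:, cols]
        if baseline:
            X = np.column_stack([X, np.ones(y.size)])
        return X

    cols = list(range(n_shift))
    coef, se, tstat, pval, rss, df = _nnls_tests(y, _design(cols),
                                                 list(templates.shifts))
    if refit:
        kept = [c for c in cols if coef[c] > 0 and pval[c] < alpha]
        if kept:
            kshifts = [templates.shifts[c] for c in kept]
            kcoef, kse, kt, kp, rss, df = _nnls_tests(y, _design(kept), kshifts)
            coef = np.zeros(n_shift + (1 if baseline else 0))
            se = np.full_like(coef, np.nan)
            tstat = np.zeros_like(coef)
            pval = np.ones(coef.shape)
            for j, c in enumerate(kept):
                coef[c], se[c], tstat[c], pval[c] = kcoef[j], kse[j], kt[j], kp[j]
            if baseline:
                coef[-1], se[-1], tstat[-1], pval[-1] = kcoef[-1], kse[-1], kt[-1], kp[-1]
    if baseline:
        coef, se, tstat, pval = coef[:-1], se[:-1], tstat[:-1], pval[:-1]
    if bonferroni:
        n_tests = max(n_shift - 1, 1)
        pval = np.where(np.isnan(se), pval, np.minimum(pval * n_tests, 1.0))

    total = coef.sum()
    fractions = coef / total if total > 0 else np.zeros_like(coef)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    return DecompositionResult(list(templates.shifts), coef, fractions, se, tstat,
                               pval, r2, df, alpha, templates)


def summarize_indels(result: DecompositionResult, substrate=None) -> Dict:
    """Interpret a decomposition in repeat expansion/contraction terms.

    Reports the dominant significant non-zero-shift component, total
    insertion and shortening signal, and — when a substrate is supplied —
    whether the dominant insert matches the loop complement (expansion) or
    the dominant deletion matches the loop length (contraction).  Signal is
    reported under both normalizations: as a fraction of the decomposed
    signal and rescaled by R^2 (fraction of the total trace including the
    unexplained residual).
    """
    sig = result.significant_shifts
    shifts = np.array(result.shifts)
    fr = result.fractions
    ins_signal = float(fr[shifts > 0].sum())
    del_signal = float(fr[shifts < 0].sum())
    summary: Dict = {
        "significant_shifts": sig,
        "insertion_signal": ins_signal,
        "shortening_signal": del_signal,
        "insertion_signal_incl_residual": ins_signal * result.r_squared,
        "shortening_signal_incl_residual": del_signal * result.r_squared,
        "r_squared": result.r_squared,
    }
    if not sig:
        summary.update({"dominant_shift": None, "dominant_fraction": 0.0,
                        "call": "no significant indel"})
        return summary
    dom = max(sig, key=result.fraction)
    summary["dominant_shift"] = int(dom)
    summary["dominant_fraction"] = result.fraction(dom)
    if dom > 0:
        call = f"+{dom} nt insertion"
        if result.templates is not None:
            ins = result.templates.inserted_bases(dom)
            summary["dominant_insert"] = ins
            if substrate is not None:
                from nickloop.substrates import revcomp
                loop = substrate.loop.loop_sequence
                summary["insert_matches_loop_complement"] = ins == revcomp(loop)
                summary["insert_matches_loop"] = ins == loop
                if ins == revcomp(loop):
                    call += " matching the loop complement (expansion)"
    else:
        call = f"{dom} nt deletion"
        if substrate is not None and -dom == substrate.L:
            summary["deletion_matches_loop_length"] = True
            call += " matching the loop length (contraction)"
    summary["call"] = call
    return summary


def plot_decomposition(mutant: Chromatogram, templates: TemplateSet,
                       result: DecompositionResult, path) -> None:
    """Two-panel figure: window trace overlay and per-shift fraction bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w0, w1 = templates.window
    fit = templates.design_matrix() @ result.coefficients
    fit = fit.reshape(-1, 4)
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(8, 6))
    colors = {"A": "green", "C": "blue", "G": "black", "T": "red"}
    x = np.arange(w0, w1)
    for ci, base in enumerate(CHANNELS):
        ax0.plot(x, mutant.scans[w0:w1, ci], color=colors[base], lw=0.7, label=base)
        ax0.plot(x, fit[:, ci], color=colors[base], lw=0.7, ls="--", alpha=0.6)
    ax0.set_xlabel("scan")
    ax0.set_ylabel("intensity")
    ax0.set_title("mutant trace (solid) vs fitted mixture (dashed)")
    ax0.legend(ncol=4, fontsize=8)
    bar_colors = ["tab:red" if s in result.significant_shifts else
                  ("tab:gray" if s else "tab:blue") for s in result.shifts]
    ax1.bar(result.shifts, 100.0 * result.fractions, color=bar_colors)
    ax1.set_xlabel("indel shift (nt)")
    ax1.set_ylabel("% of decomposed signal")
    ax1.set_title(f"R^2 = {result.r_squared:.4f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
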