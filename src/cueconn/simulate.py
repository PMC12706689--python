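"""Synthetic data with known ground truth.

Two generators drive testing of the whole pipeline:

* stable vector-autoregressive (VAR) epochs with a known directed coupling
  graph, optionally corrupted with unit-root channels to exercise the
  differencing policy;
* behavioral trial tables matching the odor-naming design: 40 participants
  in two counterbalanced groups of 12 odors, 6 repetitions, 36 trials per
  cue type (72 per participant, 2,880 in total at n = 40).

Every generator is deterministic under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = [
    "VarSpec",
    "simulate_var_epochs",
    "inject_unit_root",
    "generate_trials",
    "planted_spec",
    "simulate_subject_cohort",
    "ODORS_GROUP1",
    "ODORS_GROUP2",
]

#: counterbalanced odor sets (Sniffin' Sticks labels)
ODORS_GROUP1 = ["Coconut", "Anise", "Lemon", "Lavender", "Mushroom", "Grass"]
ODORS_GROUP2 = ["Caramel", "Cola", "Banana", "Eucalyptus", "Onion", "Rose"]


# ---------------------------------------------------------------------------
# VAR process specification
# ---------------------------------------------------------------------------

@dataclass
class VarSpec:
    """A stable VAR(p) process specification.

    ``coeffs`` is a sequence of ``p`` square matrices; the lag-``l`` entry
    ``[j, k]`` is the influence of channel ``k`` at lag ``l`` on channel
    ``j``.  The spec is rejected at construction if the companion-matrix
    spectral radius is >= 1 (non-stationary process) or if the innovation
    covariance is not symmetric positive definite.
    """

    coeffs: list[np.ndarray]
    noise_cov: np.ndarray | None = None
    intercept: np.ndarray | None = None

    n_channels: int = field(init=False)
    order: int = field(init=False)

    def __post_init__(self) -> None:
        self.coeffs = [np.asarray(A, dtype=float) for A in self.coeffs]
        if not self.coeffs:
            raise ValueError("need at least one coefficient matrix")
        c = self.coeffs[0].shape[0]
        for A in self.coeffs:
            if A.shape != (c, c):
                raise ValueError("all coefficient matrices must be square and of identical shape")
        self.n_channels = c
        self.order = len(self.coeffs)
        if self.noise_cov is None:
            self.noise_cov = np.eye(c)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.noise_cov.shape != (c, c):
            raise ValueError("noise_cov shape mismatch")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        try:
            self._chol = np.linalg.cholesky(self.noise_cov)
        except np.linalg.LinAlgError:
            raise ValueError("noise_cov must be positive definite") from None
        if self.intercept is None:
            self.intercept = np.zeros(c)
        self.intercept = np.asarray(self.intercept, dtype=float).reshape(c)
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise ValueError(
                f"unstable VAR spec: companion spectral radius {rho:.3f} >= 1"
            )

    def spectral_radius(self) -> float:
        c, p = self.n_channels, self.order
        comp = np.zeros((c * p, c * p))
        for l, A in enumerate(self.coeffs):
            comp[:c, l * c:(l + 1) * c] = A
        if p > 1:
            comp[c:, :-c] = np.eye(c * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Directed ground-truth couplings (source, target), off-diagonal."""
        out = set()
        for A in self.coeffs:
            src, tgt = np.nonzero(A.T)
            for s, t in zip(src, tgt):
                if s != t:
                    out.add((int(s), int(t)))
        return out


def simulate_var_epochs(
    spec: VarSpec,
    n_epochs: int = 36,
    epoch_duration: float = 4.0,
    srate: float = 500.0,
    seed: int = 0,
    channel_labels: list[str] | None = None,
    subject_id: str = "S00",
    condition: str = "lexical",
) -> EpochSet:
    """Draw independent stationary epochs from a stable VAR spec.

    Each epoch starts from a fresh burn-in of at least ``10 * order``
    samples (discarded), so epochs are independent realizations from the
    stationary distribution.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if srate <= 0:
        raise ValueError("srate must be positive")
    rng = np.random.default_rng(seed)
    c, p = spec.n_channels, spec.order
    n_samp = int(round(srate * epoch_duration))
    burn = max(10 * p, 50)
    total = burn + n_samp
    data = np.empty((n_epochs, c, n_samp))
    for e in range(n_epochs):
        innov = rng.standard_normal((total, c)) @ spec._chol.T
        x = np.zeros((total, c))
        for t in range(total):
            acc = spec.intercept + innov[t]
            for l in range(1, min(p, t) + 1):
                acc = acc + spec.coeffs[l - 1] @ x[t - l]
            x[t] = acc
        data[e] = x[burn:].T
    return EpochSet(
        data,
        srate=srate,
        channel_labels=channel_labels or [f"ch{i}" for i in range(c)],
        subject_id=subject_id,
        condition=condition,
        epoch_duration=epoch_duration,
    )


def inject_unit_root(
    epochs: EpochSet,
    channels: list[str],
    mode: str = "random_walk",
    seed: int = 0,
) -> EpochSet:
    """Replace channels by their within-epoch cumulative sum (once or twice).

    ``random_walk`` integrates once; ``double_integrated`` twice.  Other
    channels are untouched.  ``seed`` is accepted for interface symmetry;
    the operation itself is deterministic in the input.
    """
    if mode not in ("random_walk", "double_integrated"):
        raise ValueError(f"unknown mode {mode!r}")
    idx = [epochs.channel_index(ch) for ch in channels]
    data = epochs.data.copy()
    for i in idx:
        data[:, i, :] = np.cumsum(data[:, i, :], axis=-1)
        if mode == "double_integrated":
            data[:, i, :] = np.cumsum(data[:, i, :], axis=-1)
    return epochs.copy_with(data=data)


# ---------------------------------------------------------------------------
# benchmark cohort helpers
# ---------------------------------------------------------------------------

def planted_spec(
    n_channels: int = 6,
    order: int = 2,
    edges: list[tuple[int, int]] | None = None,
    coupling: float = 0.4,
    self_lag1: float = 0.3,
    self_lag2: float = 0.15,
) -> VarSpec:
    """A stable VAR(2) with a fixed set of planted directed edges.

    Defaults plant five edges 0->1, 0->2, 1->3, 2->4, 4->5 at lag-1
    coupling 0.4 over AR self-dynamics, a structure containing chains so
    that conditional Granger causality must suppress indirect paths.
    """
    if edges is None:
        edges = [(s, t) for s, t in [(0, 1), (0, 2), (1, 3), (2, 4), (4, 5)]
                 if s < n_channels and t < n_channels]
    A = [np.eye(n_channels) * self_lag1]
    for _ in range(order - 1):
        A.append(np.eye(n_channels) * self_lag2)
    for s, t in edges:
        A[0][t, s] = coupling
    return VarSpec(A)


def simulate_subject_cohort(
    spec: VarSpec,
    n_subjects: int = 40,
    n_epochs: int = 12,
    epoch_duration: float = 2.0,
    srate: float = 500.0,
    coeff_jitter: float = 0.02,
    seed: int = 0,
    condition: str = "lexical",
) -> list[EpochSet]:
    """Generate per-subject epoch sets from one spec plus subject noise.

    Each subject receives coefficients jittered by N(0, coeff_jitter);
    draws that would destabilize the process are shrunk until stable.
    """
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(2 * n_subjects)
    out = []
    for i in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[2 * i])
        jitter = coeff_jitter
        sspec = None
        while sspec is None:
            try:
                coeffs = [A + rng.standard_normal(A.shape) * jitter
                          for A in spec.coeffs]
                sspec = VarSpec(coeffs, spec.noise_cov, spec.intercept)
            except ValueError:
                jitter *= 0.5
        out.append(
            simulate_var_epochs(
                sspec, n_epochs=n_epochs, epoch_duration=epoch_duration,
                srate=srate, seed=int(subject_seeds[2 * i + 1]),
                subject_id=f"S{i:02d}", condition=condition,
            )
        )
    return out


# ---------------------------------------------------------------------------
# behavioral trial generator
# ---------------------------------------------------------------------------

#: Table-1 marginal rates of the naming task, used as generator defaults:
#: (P(no answer), P(correct)) per cue condition.
DEFAULT_NO_ANSWER = {"color": 442 / 1440, "lexical": 439 / 1440}
DEFAULT_ACCURACY = {"color": 258 / 1440, "lexical": 763 / 1440}


def generate_trials(
    n_participants: int = 40,
    accuracy_by_cue: tuple[float, float] | None = None,
    no_answer_by_cue: tuple[float, float] | None = None,
    rating_effects: dict | None = None,
    odor_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a behavioral trial table with the odor-naming design.

    Parameters
    ----------
    n_participants : even int
        Half are assigned to each counterbalance group (group 1 sees the
        first odor set with lexical cues, group 2 the reverse pairing).
    accuracy_by_cue : (float, float)
        Marginal P(correct) for (lexical, color); defaults to the naming
        task's observed rates 763/1440 and 258/1440.
    no_answer_by_cue : (float, float)
        Marginal P(no answer) for (lexical, color); defaults to the
        observed 439/1440 and 442/1440.
    rating_effects : dict
        Coefficients linking ratings to performance.  Keys (defaults):
        ``acc_familiarity`` (0.25), ``acc_liking`` (0.10) on the log-odds
        of a correct answer; ``rt_familiarity`` (-0.08), ``rt_liking``
        (-0.03) on log response time (negative: familiar/liked odors are
        named faster).
    odor_sd : float
        SD of optional per-odor random intercepts on the accuracy log-odds
        (0 disables odor-level structure).
    seed : int

    Returns
    -------
    DataFrame with columns participant_id, counterbalance_group, cue_type,
    odor, repetition, response_category (0 no answer / 1 incorrect /
    2 correct), rt (seconds, NaN for no-answer trials), familiarity,
    liking, ton (1-9 integer ratings).
    """
    if n_participants % 2:
        raise ValueError(
            "n_participants must be even: half of the sample is assigned to "
            "each of the two counterbalance groups"
        )
    acc = dict(DEFAULT_ACCURACY)
    if accuracy_by_cue is not None:
        acc = {"lexical": accuracy_by_cue[0], "color": accuracy_by_cue[1]}
    noans = dict(DEFAULT_NO_ANSWER)
    if no_answer_by_cue is not None:
        noans = {"lexical": no_answer_by_cue[0], "color": no_answer_by_cue[1]}
    for d in (acc, noans):
        for v in d.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
    eff = {
        "acc_familiarity": 0.25,
        "acc_liking": 0.10,
        "rt_familiarity": -0.08,
        "rt_liking": -0.03,
        "rt_mu": 0.45,
        "rt_sigma": 0.9,
    }
    if rating_effects:
        unknown = set(rating_effects) - set(eff)
        if unknown:
            raise ValueError(f"unknown rating_effects keys: {sorted(unknown)}")
        eff.update(rating_effects)

    rng = np.random.default_rng(seed)
    odors = {1: {"lexical": ODORS_GROUP1, "color": ODORS_GROUP2},
             2: {"lexical": ODORS_GROUP2, "color": ODORS_GROUP1}}
    odor_intercepts = {
        o: (rng.normal(0.0, odor_sd) if odor_sd > 0 else 0.0)
        for o in ODORS_GROUP1 + ODORS_GROUP2
    }

    rows = []
    for pid in range(n_participants):
        group = 1 if pid < n_participants // 2 else 2
        for cue in ("lexical", "color"):
            p_no = noans[cue]
            p_corr = acc[cue]
            # accuracy conditional on answering; guarded at the extremes
            denom = max(1.0 - p_no, 1e-12)
            p_corr_given_ans = min(p_corr / denom, 1.0)
            for odor in odors[group][cue]:
                for rep in range(1, 7):
                    fam = int(np.clip(round(rng.normal(5.5, 2.0)), 1, 9))
                    lik = int(np.clip(round(rng.normal(5.0, 2.0)), 1, 9))
                    ton = int(np.clip(round(rng.normal(5.0, 2.0)), 1, 9))
                    answered = rng.random() >= p_no
                    if not answered:
                        cat, rt = 0, np.nan
                    else:
                        if p_corr_given_ans <= 0.0:
                            p2 = 0.0
                        elif p_corr_given_ans >= 1.0:
                            p2 = 1.0
                        else:
                            logit = np.log(p_corr_given_ans / (1 - p_corr_given_ans))
                            logit += (
                                eff["acc_familiarity"] * (fam - 5.5)
                                + eff["acc_liking"] * (lik - 5.0)
                                + odor_intercepts[odor]
                            )
                            p2 = 1.0 / (1.0 + np.exp(-logit))
                        cat = 2 if rng.random() < p2 else 1
                        log_rt = (
                            eff["rt_mu"]
                            + eff["rt_familiarity"] * (fam - 5.5)
                            + eff["rt_liking"] * (lik - 5.0)
                            + eff["rt_sigma"] * rng.standard_normal()
                        )
                        rt = float(np.exp(log_rt))
                    rows.append(
                        (f"P{pid:02d}", group, cue, odor, rep, cat, rt,
                         fam, lik, ton)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "counterbalance_group", "cue_type", "odor",
            "repetition", "response_category", "rt", "familiarity",
            "liking", "ton",
        ],
    )
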