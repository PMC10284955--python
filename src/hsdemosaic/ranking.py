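"""Pairwise-preference ranking of demosaicking methods.

When no ground truth exists (real intraoperative snapshots), methods
are compared by a forced-choice pairwise user study: raters see two
reconstructions of the same scene and pick the better one. This module
provides

* :class:`VoteTable` — the K×K win-count matrix from such a study;
* :class:`BradleyTerry` — maximum-likelihood fitting of the
  Bradley-Terry model P(i beats j) = pi_i / (pi_i + pi_j) via the
  standard MM (Zermelo) iteration, exposed in the fitted-model style:
  ``BradleyTerry(votes).fit()`` returns a :class:`BTResult` whose
  ``pi`` sums to one;
* :func:`build_pairwise_survey` — deterministic generation of the
  question sheets (every image × every unordered method pair, shuffled
  and split into balanced surveys, left/right placement randomised).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["VoteTable", "BradleyTerry", "BTResult", "build_pairwise_survey"]


@dataclass(frozen=True)
class VoteTable:
    """Win counts from forced-choice pairwise comparisons.

    ``wins[i, j]`` is the number of times method i was preferred over
    method j; the diagonal is zero. The total comparisons of a pair are
    ``wins[i, j] + wins[j, i]``.
    """

    methods: tuple[str, ...]
    wins: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wins, dtype=np.float64)
        K = len(self.methods)
        if w.shape != (K, K):
            raise ValueError(f"wins must be {K}×{K}; got {w.shape}")
        if np.any(w < 0) or np.any(w != np.round(w)):
            raise ValueError("wins must be non-negative integers")
        if np.any(np.diag(w) != 0):
            raise ValueError("wins diagonal must be zero")
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "wins", w)

    @property
    def n_methods(self) -> int:
        return len(self.methods)

    # -- CSV interchange: columns method_a, method_b, wins_a, wins_b ----
    @classmethod
    def from_csv(cls, path: str | Path) -> "VoteTable":
        df = pd.read_csv(path)
        methods: list[str] = []
        for col in ("method_a", "method_b"):
            for m in df[col]:
                if m not in methods:
                    methods.append(m)
        idx = {m: i for i, m in enumerate(methods)}
        wins = np.zeros((len(methods), len(methods)))
        for _, row in df.iterrows():
            a, b = idx[row["method_a"]], idx[row["method_b"]]
            wins[a, b] += row["wins_a"]
            wins[b, a] += row["wins_b"]
        return cls(methods=tuple(methods), wins=wins)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "method_a": self.methods[i],
                "method_b": self.methods[j],
                "wins_a": int(self.wins[i, j]),
                "wins_b": int(self.wins[j, i]),
            }
            for i, j in combinations(range(self.n_methods), 2)
            if self.wins[i, j] + self.wins[j, i] > 0
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class BTResult:
    """Fitted Bradley-Terry preference scale.

    ``pi`` holds one positive strength per method, normalised to sum to
    one: pi_i / (pi_i + pi_j) is the fitted probability that method i
    wins a comparison against method j.
    """

    methods: tuple[str, ...]
    pi: np.ndarray
    iterations: int
    converged: bool
    log_likelihood: float

    def summary(self) -> str:
        order = np.argsort(self.pi)[::-1]
        lines = [
            "Bradley-Terry preference scale",
            "=" * 34,
            f"converged: {self.converged} ({self.iterations} iterations)",
            f"log-likelihood: {self.log_likelihood:.4f}",
            "",
            f"{'method':<16s} {'pi':>8s}",
        ]
        for i in order:
            lines.append(f"{self.methods[i]:<16s} {self.pi[i]:>8.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "pi": [float(p) for p in self.pi],
            "iterations": self.iterations,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
        }


class BradleyTerry:
    """Maximum-likelihood Bradley-Terry model for a vote table.

    ``fit`` runs the MM (Zermelo) iteration
    pi_i <- W_i / sum_j n_ij / (pi_i + pi_j), renormalising each sweep;
    it converges for any connected comparison graph in which every
    method has at least one win and one loss.
    """

    def __init__(self, votes: VoteTable):
        self.votes = votes
        self._validate()

    def _validate(self) -> None:
        w = self.votes.wins
        K = self.votes.n_methods
        if K < 2:
            raise ValueError("ranking requires at least two methods")
        total_w = w.sum(axis=1)
        total_l = w.sum(axis=0)
        if np.any(total_w == 0) or np.any(total_l == 0):
            bad = [
                self.votes.methods[i]
                for i in range(K)
                if total_w[i] == 0 or total_l[i] == 0
            ]
            raise ValueError(
                f"method(s) {bad} have no win or no loss; the maximum-"
                "likelihood strengths are degenerate (0 or infinite)"
            )
        # connectivity of the comparison graph (BFS on n_ij > 0)
        n = w + w.T
        seen = {0}
        frontier = [0]
        while frontier:
            i = frontier.pop()
            for j in np.nonzero(n[i] > 0)[0]:
                if j not in seen:
                    seen.add(int(j))
                    frontier.append(int(j))
        if len(seen) != K:
            missing = [self.votes.methods[i] for i in range(K) if i not in seen]
            raise ValueError(
                f"comparison graph is disconnected (no path to {missing}); "
                "relative strengths across components are unidentifiable"
            )

    def fit(self, tol: float = 1e-10, max_iter: int = 10000) -> BTResult:
        w = self.votes.wins
        K = self.votes.n_methods
        n = w + w.T
        W = w.sum(axis=1)
        pi = np.full(K, 1.0 / K)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            denom = (n / (pi[:, None] + pi[None, :] + np.eye(K))).sum(axis=1)
            # the eye term only touches the diagonal, where n is 0
            new = W / denom
            new /= new.sum()
            delta = float(np.max(np.abs(new - pi)))
            pi = new
            if delta < tol:
                converged = True
                break
        ll = self.log_likelihood(pi)
        return BTResult(
            methods=self.votes.methods,
            pi=pi,
            iterations=it,
            converged=converged,
            log_likelihood=ll,
        )

    def log_likelihood(self, pi: np.ndarray) -> float:
        """Bernoulli log-likelihood of the vote table under strengths pi."""
        w = self.votes.wins
        K = self.votes.n_methods
        ll = 0.0
        for i in range(K):
            for j in range(K):
                if i != j and w[i, j] > 0:
                    ll += w[i, j] * np.log(pi[i] / (pi[i] + pi[j]))
        return float(ll)


def build_pairwise_survey(
    images: list[str],
    methods: list[str],
    n_surveys: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate forced-choice question sheets.

    One question per (image, unordered method pair): K methods give
    K(K-1)/2 questions per image. Questions are shuffled
    deterministically under ``seed``, left/right placement is
    randomised, and the set is split into ``n_surveys`` balanced
    surveys. Returns a DataFrame with columns (survey, question, image,
    left, right).
    """
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    rng = np.random.default_rng(seed)
    questions = [
        (img, a, b) for img in images for a, b in combinations(methods, 2)
    ]
    order = rng.permutation(len(questions))
    rows = []
    for pos, qi in enumerate(order):
        img, a, b = questions[qi]
        if rng.integers(2):
            a, b = b, a
        rows.append(
            {
                "survey": pos % n_surveys,
                "question": pos // n_surveys,
                "image": img,
                "left": a,
                "right": b,
            }
        )
    return pd.DataFrame(rows).sort_values(["survey", "question"]).reset_index(drop=True)
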