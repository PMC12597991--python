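"""Model design language for the multi-event model: parameter forms,
sharing constraints, and compilation to a flat coefficient vector.

The hidden-Markov model lives on eight ordered states

    J, SA, NB-, NB+, B-, B+, FD, D

(juvenile, subadult, non-breeder / breeder of low (-) or high (+) latent
quality, freshly dead, dead) and six ordered events

    0 (not observed), J, SA, NB, B, D (recovered dead).

Each structural parameter (survival ``phi``, arrival ``psi_b``, departure
``psi_nb``, recruitment ``psi_r``, detection ``p``, ``p_sa``, dead recovery
``p_fd``) is given a *form*: constant, age-linear-logistic,
age-quadratic-logistic, an age factor over bins, or (for detection targets)
a year / year-block factor, optionally stratified by latent quality and/or
breeding state.  Two-outcome rows use a plain logit link.  The juvenile row
has three tied exit routes (to SA, B-, B+), so recruitment uses a
multinomial-logit link with the "remain juvenile" cell as reference,

    psi_r = exp(eta) / (1 + 3 exp(eta)),

which keeps the row stochastic (psi_r < 1/3) for every finite coefficient.

Age enters link functions uncentered, in years, so slopes are in
logits per year of age.  Purely for numerical conditioning the optimizer
works on a centred/scaled basis u = (age - 20)/10; the compiled design
carries the exact affine map between the two bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "STATES",
    "EVENTS",
    "N_STATES",
    "N_EVENTS",
    "ParamForm",
    "ModelDesign",
    "CompiledDesign",
    "logistic_age",
    "expit",
    "logit",
    "mlogit3",
    "mlogit3_inv",
    "linear_logistic_through",
    "quadratic_logistic_through",
    "assemble_phi",
    "assemble_psi",
    "assemble_event",
    "build_matrices",
    "paper_year_blocks",
    "DEFAULT_AGE_BINS",
]

STATES = ("J", "SA", "NB-", "NB+", "B-", "B+", "FD", "D")
EVENTS = ("0", "J", "SA", "NB", "B", "D")
N_STATES = 8
N_EVENTS = 6

# state indices
J, SA, NBm, NBp, Bm, Bp, FD, D = range(8)

AGE_CENTER = 20.0
AGE_SCALE = 10.0


def expit(x):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def mlogit3(eta):
    """Juvenile-row multinomial-logit inverse link: exp(eta)/(1+3exp(eta)) < 1/3."""
    eta = np.asarray(eta, dtype=float)
    return np.where(
        eta >= 0,
        1.0 / (3.0 + np.exp(-eta)),
        np.exp(eta) / (1.0 + 3.0 * np.exp(eta)),
    )


def mlogit3_inv(p):
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1.0 / 3.0):
        raise ValueError("recruitment probability must lie in (0, 1/3)")
    return np.log(p / (1.0 - 3.0 * p))


def logistic_age(coeffs: Sequence[float], age) -> np.ndarray | float:
    """expit(b0 + b1*age [+ b2*age**2]); strictly inside (0, 1).

    ``coeffs`` must have exactly 2 (linear) or 3 (quadratic) entries.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    age = np.asarray(age, dtype=float)
    if coeffs.shape == (2,):
        eta = coeffs[0] + coeffs[1] * age
    elif coeffs.shape == (3,):
        eta = coeffs[0] + coeffs[1] * age + coeffs[2] * age**2
    else:
        raise ValueError(
            f"expected 2 (linear) or 3 (quadratic) coefficients, got {coeffs.shape}"
        )
    out = expit(eta)
    return float(out) if out.ndim == 0 else out


def linear_logistic_through(pt1, pt2, link_inv=None, link=None):
    """(b0, b1) of the linear form passing through two (age, probability) anchors."""
    to_eta = link if link is not None else logit
    (x1, p1), (x2, p2) = pt1, pt2
    e1, e2 = float(to_eta(p1)), float(to_eta(p2))
    b1 = (e2 - e1) / (x2 - x1)
    return (e1 - b1 * x1, b1)


def quadratic_logistic_through(pt1, pt2, vertex, link=None):
    """(b0, b1, b2) of a quadratic form through two anchors with a given vertex age."""
    to_eta = link if link is not None else logit
    (x1, p1), (x2, p2) = pt1, pt2
    e1, e2 = float(to_eta(p1)), float(to_eta(p2))
    # eta = b0 + b2*(x^2 - 2*vertex*x); solve b2 from the two anchors
    g1 = x1**2 - 2 * vertex * x1
    g2 = x2**2 - 2 * vertex * x2
    b2 = (e1 - e2) / (g1 - g2)
    b0 = e1 - b2 * g1
    return (b0, -2 * vertex * b2, b2)


def paper_year_blocks(first_year: int, last_year: int) -> list[tuple[int, int]]:
    """Detection-year blocks around known periods of change (facility setup,
    the 2001 hurricane): [first,1984], [1985,2001], [2002,2003], [2004,last].
    Blocks outside the occasion range are dropped."""
    cuts = [(first_year, 1984), (1985, 2001), (2002, 2003), (2004, last_year)]
    out = [(max(lo, first_year), min(hi, last_year)) for lo, hi in cuts]
    return [(lo, hi) for lo, hi in out if lo <= hi]


DEFAULT_AGE_BINS: list[tuple[int, int]] = [(0, 6)] + [(a, a) for a in range(7, 36)] + [(36, 45)]

_AGE_FORMS = ("constant", "linear", "quadratic", "factor")
_TIME_FORMS = ("constant", "year", "blocks")
_TARGETS = ("phi", "psi_r", "psi_b", "psi_nb", "p", "p_sa", "p_fd")


@dataclass(frozen=True)
class ParamForm:
    """Functional form for one structural parameter.

    ``fixed`` pins the parameter at a probability (no coefficient estimated);
    age forms apply to phi / psi_* targets, time forms to detection targets.
    """

    target: str
    age: str = "constant"
    time: str = "constant"
    by_quality: bool = False
    by_state: bool = False
    age_bins: tuple[tuple[int, int], ...] | None = None
    fixed: float | None = None

    def __post_init__(self):
        if self.target not in _TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.age not in _AGE_FORMS:
            raise ValueError(f"unknown age form {self.age!r}")
        if self.time not in _TIME_FORMS:
            raise ValueError(f"unknown time form {self.time!r}")
        if self.target in ("p", "p_sa", "p_fd") and self.age != "constant":
            raise ValueError(f"{self.target} cannot carry an age form")
        if self.target in ("phi", "psi_r", "psi_b", "psi_nb") and self.time != "constant":
            raise ValueError(f"{self.target} cannot carry a time form")
        if self.by_state and self.target not in ("phi", "p"):
            raise ValueError("state stratification applies to phi and p only")
        if self.by_quality and self.target in ("psi_r", "p_sa", "p_fd"):
            raise ValueError(f"{self.target} cannot be stratified by quality")
        if self.target == "psi_r" and self.age in ("linear", "factor"):
            warnings.warn(
                "recruitment (psi_r) with a linear/factor age form: movement to "
                "the breeder tank is not a biological process; consider constant "
                "or quadratic",
                stacklevel=2,
            )


def _default_forms() -> dict[str, ParamForm]:
    return {
        "phi": ParamForm("phi"),
        "psi_r": ParamForm("psi_r"),
        "psi_b": ParamForm("psi_b"),
        "psi_nb": ParamForm("psi_nb"),
        "p": ParamForm("p"),
        "p_sa": ParamForm("p_sa", fixed=1.0),
        "p_fd": ParamForm("p_fd"),
    }


@dataclass
class ModelDesign:
    """One ParamForm per structural parameter plus shared metadata.

    The recruitment tie (psi_JB- = psi_JB+ = psi_SAB- = psi_SAB+ = psi_SA
    = psi_r) is built in, as is quality-class immutability (zero probability
    of moving between - and +).
    """

    forms: dict[str, ParamForm] = field(default_factory=_default_forms)
    year_blocks: list[tuple[int, int]] | None = None
    name: str = "design"

    def __post_init__(self):
        base = _default_forms()
        base.update(self.forms)
        self.forms = base

    def with_form(self, form: ParamForm) -> "ModelDesign":
        forms = dict(self.forms)
        forms[form.target] = form
        return ModelDesign(forms=forms, year_blocks=self.year_blocks, name=self.name)

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "year_blocks": [list(b) for b in self.year_blocks] if self.year_blocks else None,
            "forms": {
                t: {
                    "age": f.age,
                    "time": f.time,
                    "by_quality": f.by_quality,
                    "by_state": f.by_state,
                    "age_bins": [list(b) for b in f.age_bins] if f.age_bins else None,
                    "fixed": f.fixed,
                }
                for t, f in self.forms.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelDesign":
        forms = {}
        for t, f in d.get("forms", {}).items():
            forms[t] = ParamForm(
                target=t,
                age=f.get("age", "constant"),
                time=f.get("time", "constant"),
                by_quality=f.get("by_quality", False),
                by_state=f.get("by_state", False),
                age_bins=tuple(tuple(b) for b in f["age_bins"]) if f.get("age_bins") else None,
                fixed=f.get("fixed"),
            )
        yb = d.get("year_blocks")
        return cls(
            forms=forms,
            year_blocks=[tuple(b) for b in yb] if yb else None,
            name=d.get("name", "design"),
        )

    def compile(self, occasion_range: tuple[int, int], max_age: int | None = None) -> "CompiledDesign":
        return CompiledDesign(self, occasion_range, max_age)


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

_QUALITY = ("low", "high")
_STATE = ("NB", "B")


@dataclass(frozen=True)
class _Block:
    """One run of coefficients: a (target, stratum) cell with a given form kind."""

    target: str
    stratum: str  # "", "low", "NB", "low|NB", ...
    kind: str  # constant / linear / quadratic / factor / time
    size: int
    offset: int
    labels: tuple[str, ...]
    bins: tuple[tuple[int, int], ...] | None = None  # age bins or year blocks


class CompiledDesign:
    """A ModelDesign bound to an occasion range: flat coefficient vector of
    length K, labels, per-age / per-year probability schedules, and the
    affine map between the raw-age and scaled optimization bases."""

    def __init__(self, design: ModelDesign, occasion_range: tuple[int, int], max_age: int | None = None):
        self.design = design
        self.first_year, self.last_year = occasion_range
        self.n_years = self.last_year - self.first_year + 1
        self.max_age = int(max_age) if max_age is not None else self.n_years - 1
        self.n_ages = self.max_age + 1
        self.year_blocks = design.year_blocks or paper_year_blocks(self.first_year, self.last_year)
        self.blocks: list[_Block] = []
        self.labels: list[str] = []
        self._build_blocks()
        self.K = len(self.labels)

    # --- block layout ------------------------------------------------------
    def _strata(self, form: ParamForm) -> list[str]:
        if form.by_quality and form.by_state:
            return [f"{q}|{s}" for q in _QUALITY for s in _STATE]
        if form.by_quality:
            return list(_QUALITY)
        if form.by_state:
            return list(_STATE)
        return [""]

    def _build_blocks(self) -> None:
        for target in _TARGETS:
            form = self.design.forms[target]
            if form.fixed is not None:
                continue
            for stratum in self._strata(form):
                tag = f"{target}[{stratum}]" if stratum else target
                if target in ("p", "p_sa", "p_fd"):
                    if form.time == "constant":
                        kind, bins = "constant", None
                        labels = (f"{tag}:b0",)
                    elif form.time == "blocks":
                        kind = "time"
                        bins = tuple(self.year_blocks)
                        labels = tuple(f"{tag}:{lo}-{hi}" for lo, hi in bins)
                    else:  # year
                        kind = "time"
                        bins = tuple((y, y) for y in range(self.first_year, self.last_year + 1))
                        labels = tuple(f"{tag}:{y}" for y, _ in bins)
                else:
                    if form.age == "constant":
                        kind, bins = "constant", None
                        labels = (f"{tag}:b0",)
                    elif form.age == "linear":
                        kind, bins = "linear", None
                        labels = (f"{tag}:b0", f"{tag}:b1")
                    elif form.age == "quadratic":
                        kind, bins = "quadratic", None
                        labels = (f"{tag}:b0", f"{tag}:b1", f"{tag}:b2")
                    else:  # factor
                        kind = "factor"
                        bins = tuple(form.age_bins or DEFAULT_AGE_BINS)
                        bins = tuple((lo, min(hi, self.max_age)) for lo, hi in bins if lo <= self.max_age)
                        labels = tuple(f"{tag}:{lo}-{hi}" if lo != hi else f"{tag}:{lo}" for lo, hi in bins)
                self.blocks.append(
                    _Block(target, stratum, kind, len(labels), len(self.labels), labels, bins)
                )
                self.labels.extend(labels)

    # --- basis transforms --------------------------------------------------
    def transform_matrix(self) -> np.ndarray:
        """T with theta_raw = T @ theta_internal (exact, affine)."""
        T = np.eye(self.K)
        c, s = AGE_CENTER, AGE_SCALE
        for b in self.blocks:
            i = b.offset
            if b.kind == "linear":
                # b0 + b1*x == i0 + i1*(x-c)/s
                T[i : i + 2, i : i + 2] = [[1.0, -c / s], [0.0, 1.0 / s]]
            elif b.kind == "quadratic":
                T[i : i + 3, i : i + 3] = [
                    [1.0, -c / s, c**2 / s**2],
                    [0.0, 1.0 / s, -2 * c / s**2],
                    [0.0, 0.0, 1.0 / s**2],
                ]
        return T

    def to_internal(self, theta_raw: np.ndarray) -> np.ndarray:
        return np.linalg.solve(self.transform_matrix(), np.asarray(theta_raw, float))

    def from_internal(self, theta_internal: np.ndarray) -> np.ndarray:
        return self.transform_matrix() @ np.asarray(theta_internal, float)

    # --- schedules ---------------------------------------------------------
    def _eval_block(self, b: _Block, coeffs: np.ndarray) -> np.ndarray:
        """Linear predictor over ages (age blocks) or years (time blocks)."""
        if b.target in ("p", "p_sa", "p_fd"):
            eta = np.empty(self.n_years)
            if b.kind == "constant":
                eta[:] = coeffs[0]
            else:
                for (lo, hi), c in zip(b.bins, coeffs):
                    eta[lo - self.first_year : hi - self.first_year + 1] = c
            return eta
        ages = np.arange(self.n_ages, dtype=float)
        if b.kind == "constant":
            return np.full(self.n_ages, coeffs[0])
        if b.kind == "linear":
            return coeffs[0] + coeffs[1] * ages
        if b.kind == "quadratic":
            return coeffs[0] + coeffs[1] * ages + coeffs[2] * ages**2
        eta = np.empty(self.n_ages)
        eta[:] = coeffs[-1]  # ages beyond the last bin inherit the last level
        for (lo, hi), c in zip(b.bins, coeffs):
            eta[lo : min(hi, self.max_age) + 1] = c
        return eta

    def schedules(self, theta_raw: np.ndarray) -> dict[str, np.ndarray]:
        """Probability schedules from a raw-basis coefficient vector.

        Returns arrays keyed by target: ``phi`` (4, n_ages) over cells
        (NB-, NB+, B-, B+); ``psi_b``/``psi_nb`` (2, n_ages) over (low, high);
        ``psi_r`` (n_ages,); ``p`` (4, n_years) over (NB-, NB+, B-, B+);
        ``p_sa``/``p_fd`` (n_years,).
        """
        theta = np.asarray(theta_raw, dtype=float)
        if theta.shape != (self.K,):
            raise ValueError(f"theta has length {theta.shape}, design needs K={self.K}")
        eta: dict[tuple[str, str], np.ndarray] = {}
        for b in self.blocks:
            eta[(b.target, b.stratum)] = self._eval_block(b, theta[b.offset : b.offset + b.size])

        def cell(target: str, quality: str, state: str, n: int) -> np.ndarray:
            form = self.design.forms[target]
            if form.fixed is not None:
                return np.full(n, float(form.fixed))
            if form.by_quality and form.by_state:
                key = f"{quality}|{state}"
            elif form.by_quality:
                key = quality
            elif form.by_state:
                key = state
            else:
                key = ""
            link = mlogit3 if target == "psi_r" else expit
            return link(eta[(target, key)])

        na, ny = self.n_ages, self.n_years
        return {
            "phi": np.stack([cell("phi", q, s, na) for s in _STATE for q in _QUALITY]),
            "psi_r": cell("psi_r", "", "", na),
            "psi_b": np.stack([cell("psi_b", q, "", na) for q in _QUALITY]),
            "psi_nb": np.stack([cell("psi_nb", q, "", na) for q in _QUALITY]),
            "p": np.stack([cell("p", q, s, ny) for s in _STATE for q in _QUALITY]),
            "p_sa": cell("p_sa", "", "", ny),
            "p_fd": cell("p_fd", "", "", ny),
        }


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


def assemble_phi(phi_cells: Sequence[float]) -> np.ndarray:
    """8x8 survival matrix from (phi_NB-, phi_NB+, phi_B-, phi_B+).

    J and SA survive with probability 1 (the likelihood conditions on
    surviving to recruitment); FD moves to D; D is absorbing.
    """
    m = np.zeros((N_STATES, N_STATES))
    m[J, J] = 1.0
    m[SA, SA] = 1.0
    for st, ph in zip((NBm, NBp, Bm, Bp), phi_cells):
        if not 0.0 <= ph <= 1.0:
            raise ValueError(f"survival probability {ph} outside [0,1]")
        m[st, st] = ph
        m[st, FD] = 1.0 - ph
    m[FD, D] = 1.0
    m[D, D] = 1.0
    return m


def assemble_psi(psi_r: float, psi_b: Sequence[float], psi_nb: Sequence[float]) -> np.ndarray:
    """8x8 transition matrix (conditional on survival) under the recruitment
    tie: the juvenile row is (1-3*psi_r, psi_r, 0, 0, psi_r, psi_r, 0, 0)."""
    if psi_r < 0 or psi_r > 1.0 / 3.0:
        raise ValueError(
            f"recruitment probability {psi_r} > 1/3 makes the juvenile row negative"
        )
    m = np.zeros((N_STATES, N_STATES))
    m[J] = [1 - 3 * psi_r, psi_r, 0, 0, psi_r, psi_r, 0, 0]
    m[SA] = [0, 1 - 2 * psi_r, 0, 0, psi_r, psi_r, 0, 0]
    m[NBm, NBm] = 1 - psi_b[0]
    m[NBm, Bm] = psi_b[0]
    m[NBp, NBp] = 1 - psi_b[1]
    m[NBp, Bp] = psi_b[1]
    m[Bm, NBm] = psi_nb[0]
    m[Bm, Bm] = 1 - psi_nb[0]
    m[Bp, NBp] = psi_nb[1]
    m[Bp, Bp] = 1 - psi_nb[1]
    m[FD, FD] = 1.0
    m[D, D] = 1.0
    return m


def assemble_event(p_cells: Sequence[float], p_sa: float, p_fd: float) -> np.ndarray:
    """8x6 event (detection) matrix from (p_NB-, p_NB+, p_B-, p_B+), p_SA, p_FD.

    Juveniles are detected as J with probability 1; D emits "not observed";
    FD emits the dead-recovery event with probability p_fd in the death year.
    """
    m = np.zeros((N_STATES, N_EVENTS))
    m[J, 1] = 1.0
    m[SA, 0], m[SA, 2] = 1 - p_sa, p_sa
    m[NBm, 0], m[NBm, 3] = 1 - p_cells[0], p_cells[0]
    m[NBp, 0], m[NBp, 3] = 1 - p_cells[1], p_cells[1]
    m[Bm, 0], m[Bm, 4] = 1 - p_cells[2], p_cells[2]
    m[Bp, 0], m[Bp, 4] = 1 - p_cells[3], p_cells[3]
    m[FD, 0], m[FD, 5] = 1 - p_fd, p_fd
    m[D, 0] = 1.0
    return m


def build_matrices(
    compiled: CompiledDesign, theta_raw: np.ndarray, age: int, year: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi, psi, p) at one age and calendar year; every row sums to 1."""
    s = compiled.schedules(theta_raw)
    a = min(int(age), compiled.max_age)
    yi = int(year) - compiled.first_year
    if yi < 0 or yi >= compiled.n_years:
        raise ValueError(f"year {year} outside occasion range")
    phi = assemble_phi(s["phi"][:, a])
    psi = assemble_psi(s["psi_r"][a], s["psi_b"][:, a], s["psi_nb"][:, a])
    p = assemble_event(s["p"][:, yi], s["p_sa"][yi], s["p_fd"][yi])
    return phi, psi, p
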