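"""Quantitation of bead-proximity (ALPHA-Screen-style) protein-protein
interaction assays.

The assay reports a luminescence signal over a serial dilution of lysate
co-expressing a tagged protein pair.  A genuine interaction produces a
bell-shaped ("hook effect") titration curve: signal rises with analyte
concentration until beads saturate, then falls.  A flat series at background
indicates no interaction.

Three quantities are derived here:

* **Binding Index (BI)** — the background-subtracted peak signal of a pair,
  normalised to a reference pair::

      BI = (I - I_neg) / (I_ref - I_neg) * 100

  where ``I`` is the top of the hook curve (maximum of per-step replicate
  means), ``I_neg`` the background signal, and ``I_ref`` the top of the
  reference pair's curve.

* **Disruption percentage** — loss of signal at a single compound
  concentration relative to vehicle: ``(1 - I_compound / I_vehicle) * 100``.

* **IC50** — from a three-parameter log-logistic fit (top, bottom, IC50;
  Hill slope fixed at 1 by default) of percent interaction
  (``I_compound / I_vehicle * 100``) versus compound concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "TitrationSeries",
    "BindingIndexResult",
    "DisruptionResult",
    "DoseResponseData",
    "DoseResponseModel",
    "DoseResponseResults",
    "binding_index",
    "call_interaction",
    "disruption_percent",
    "percent_interaction",
    "fit_ic50",
    "DEFAULT_BI_THRESHOLD",
    "DEFAULT_DISRUPTION_THRESHOLD",
]

#: Default Binding-Index threshold for calling a pair an interactor.  The
#: assay's threshold is conventional (shown only graphically in heatmap scale
#: bars); 20 on the 0-100 BI scale is the package default and is configurable
#: everywhere it is used.
DEFAULT_BI_THRESHOLD = 20.0

#: Default disruption-call threshold (percent signal loss at the single test
#: concentration).  Conventional; configurable.
DEFAULT_DISRUPTION_THRESHOLD = 25.0


@dataclass
class TitrationSeries:
    """Signal versus serial-dilution step for one protein pair.

    Parameters
    ----------
    dilution_steps
        Ordered dilution step labels (e.g. step index or lysate dilution
        factor).  Length ``n_steps``.
    signals
        ``(n_steps, n_replicates)`` luminescence matrix, arbitrary units.
    pair_id
        Optional identifier of the protein pair.
    """

    dilution_steps: np.ndarray
    signals: np.ndarray
    pair_id: str | None = None

    def __post_init__(self) -> None:
        self.dilution_steps = np.asarray(self.dilution_steps)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != self.dilution_steps.shape[0]:
            raise ValueError(
                "signals must have one row per dilution step "
                f"({self.signals.shape[0]} rows vs {len(self.dilution_steps)} steps)"
            )
        if len(self.dilution_steps) < 3:
            raise ValueError("a titration series needs at least 3 dilution steps")
        if np.any(self.signals < 0):
            raise ValueError("luminescence signals must be non-negative")

    def step_means(self) -> np.ndarray:
        """Per-step replicate means (hook curve)."""
        return self.signals.mean(axis=1)

    @property
    def top(self) -> float:
        """Top of the hook curve: maximum of per-step replicate means.

        The per-step mean (not the single brightest well) is used so one
        outlier well cannot set the peak.
        """
        return float(self.step_means().max())

    @property
    def background(self) -> float:
        """Lowest per-step replicate mean (background floor of the curve)."""
        return float(self.step_means().min())


@dataclass
class BindingIndexResult:
    """Binding index of one pair against a reference and a negative control."""

    bi: float
    i_top: float
    i_neg: float
    i_ref: float
    threshold: float
    interaction_call: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        sign = "+" if self.interaction_call else "-"
        return f"BI={self.bi:.1f} [{sign}] (I={self.i_top:.0f}, ref={self.i_ref:.0f}, neg={self.i_neg:.0f})"


@dataclass
class DisruptionResult:
    """Signal loss under compound at a single concentration."""

    disruption_pct: float
    i_compound: float
    i_vehicle: float
    threshold: float
    disruption_call: bool


def binding_index(
    series: TitrationSeries,
    ref_series: TitrationSeries,
    neg_series: TitrationSeries | None = None,
    threshold: float = DEFAULT_BI_THRESHOLD,
) -> BindingIndexResult:
    """Compute the Binding Index ``(I - I_neg)/(I_ref - I_neg) * 100``.

    ``I`` and ``I_ref`` are the hook-curve tops of `series` and `ref_series`
    (maximum per-step replicate mean).  ``I_neg`` is the background level: the
    minimum per-step mean of `neg_series` when given, else of `series` itself
    (the tails of the hook curve sit at background).

    Raises
    ------
    ValueError
        If the reference top does not exceed background (degenerate
        normalisation).
    """
    i_top = series.top
    i_neg = (neg_series if neg_series is not None else series).background
    i_ref = ref_series.top
    if i_ref <= i_neg:
        raise ValueError(
            f"degenerate reference: I_ref ({i_ref:g}) must exceed I_neg ({i_neg:g})"
        )
    bi = (i_top - i_neg) / (i_ref - i_neg) * 100.0
    return BindingIndexResult(
        bi=bi,
        i_top=i_top,
        i_neg=i_neg,
        i_ref=i_ref,
        threshold=threshold,
        interaction_call=call_interaction(bi, threshold),
    )


def call_interaction(bi: float, threshold: float = DEFAULT_BI_THRESHOLD) -> bool:
    """Interaction call: ``True`` ('+') iff ``bi >= threshold``.

    The tie goes to '+' (>= convention).
    """
    return bool(bi >= threshold)


def disruption_percent(
    i_compound: float,
    i_vehicle: float,
    threshold: float = DEFAULT_DISRUPTION_THRESHOLD,
) -> DisruptionResult:
    """Percent disruption ``(1 - I_compound / I_vehicle) * 100``.

    `i_compound` and `i_vehicle` are (replicate-averaged) signals of the same
    pair with compound and vehicle respectively.  The call is
    ``disruption_pct >= threshold``.
    """
    if i_vehicle <= 0:
        raise ValueError("vehicle signal must be positive (undefined ratio)")
    pct = (1.0 - i_compound / i_vehicle) * 100.0
    return DisruptionResult(
        disruption_pct=pct,
        i_compound=float(i_compound),
        i_vehicle=float(i_vehicle),
        threshold=threshold,
        disruption_call=bool(pct >= threshold),
    )


def percent_interaction(i_compound: float, i_vehicle: float) -> float:
    """Percent residual interaction ``I_compound / I_vehicle * 100``.

    Complement of :func:`disruption_percent`: the two sum to 100.
    """
    if i_vehicle <= 0:
        raise ValueError("vehicle signal must be positive (undefined ratio)")
    return i_compound / i_vehicle * 100.0


# ---------------------------------------------------------------------------
# dose-response fitting
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseData:
    """Percent interaction versus inhibitor concentration.

    Parameters
    ----------
    concentrations
        Inhibitor concentrations, µM, strictly positive.  Length ``n_conc``.
    responses
        ``(n_conc, n_replicates)`` percent-interaction matrix.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    pair_id: str | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if self.responses.shape[0] != self.concentrations.shape[0]:
            raise ValueError("responses must have one row per concentration")

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled (x, y) arrays with replicates flattened."""
        n_rep = self.responses.shape[1]
        x = np.repeat(self.concentrations, n_rep)
        y = self.responses.ravel()
        return x, y


def _log_logistic(x: np.ndarray, top: float, bottom: float, log_ic50: float,
                  hill: float = 1.0) -> np.ndarray:
    ic50 = np.exp(log_ic50)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


class DoseResponseModel:
    """Three-parameter log-logistic inhibition model.

    Model::

        y = bottom + (top - bottom) / (1 + (x / IC50)^h)

    with Hill slope ``h`` fixed at 1 by default ("three-parameter": top,
    bottom, IC50).  The IC50 is fitted on the log scale, which keeps it
    positive and makes the optimisation well-conditioned across the
    0.3-300 µM range.

    Parameters
    ----------
    data
        A :class:`DoseResponseData`, or pass `conc` and `response` arrays.
    """

    def __init__(self, data: DoseResponseData | None = None, *,
                 conc: np.ndarray | None = None,
                 response: np.ndarray | None = None):
        if data is None:
            if conc is None or response is None:
                raise ValueError("provide data= or both conc= and response=")
            data = DoseResponseData(np.asarray(conc), np.asarray(response))
        self.data = data
        x = data.concentrations
        if len(np.unique(x)) < 4:
            raise ValueError("need >= 4 distinct concentrations to fit 3 parameters")
        if np.log10(x.max() / x.min()) < 2:
            raise ValueError("concentration range must span >= 2 log units")

    def start_params(self) -> np.ndarray:
        """Initial (top, bottom, log IC50) from data extremes and the
        concentration nearest half-maximal response."""
        means = self.data.responses.mean(axis=1)
        top0 = float(means.max())
        bottom0 = float(means.min())
        half = (top0 + bottom0) / 2.0
        i_half = int(np.argmin(np.abs(means - half)))
        return np.array([top0, bottom0, np.log(self.data.concentrations[i_half])])

    def fit(self, fix_hill: bool = True) -> "DoseResponseResults":
        """Least-squares fit; never raises on non-convergence.

        With ``fix_hill=False`` the Hill slope is a fourth free parameter
        (sensitivity analysis); the default matches the three-parameter
        convention of standard curve-fitting software.
        """
        x, y = self.data.flat()
        p0 = list(self.start_params())
        if not fix_hill:
            p0.append(1.0)
            fun = _log_logistic
        else:
            fun = lambda x, top, bottom, log_ic50: _log_logistic(x, top, bottom, log_ic50)  # noqa: E731
        converged = True
        pcov = None
        try:
            popt, pcov = optimize.curve_fit(fun, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            popt, converged = np.asarray(p0), False
        resid = y - fun(x, *popt)
        rss = float(resid @ resid)
        return DoseResponseResults(self, popt, pcov, rss, converged,
                                   hill_fixed=fix_hill)


class DoseResponseResults:
    """Fitted dose-response parameters with uncertainties.

    Attributes
    ----------
    top, bottom : float
        Fitted asymptotes (% interaction).
    ic50 : float
        Fitted IC50, µM.
    hill : float
        Hill slope (1.0 unless fitted free).
    rss : float
        Residual sum of squares.
    converged : bool
        False when the optimiser failed; parameters then equal the start
        values and must not be trusted.
    bse : dict
        Approximate standard errors (delta method for ic50) when the
        covariance is available.
    """

    def __init__(self, model: DoseResponseModel, params: np.ndarray,
                 pcov: np.ndarray | None, rss: float, converged: bool,
                 hill_fixed: bool = True):
        self.model = model
        self.params = params
        self.top = float(params[0])
        self.bottom = float(params[1])
        self.ic50 = float(np.exp(params[2]))
        self.hill = 1.0 if hill_fixed else float(params[3])
        self.hill_fixed = hill_fixed
        self.rss = rss
        self.converged = converged
        self.bse: dict[str, float] = {}
        if pcov is not None and np.all(np.isfinite(pcov)):
            se = np.sqrt(np.diag(pcov))
            self.bse = {"top": se[0], "bottom": se[1],
                        "ic50": self.ic50 * se[2]}  # delta method on log scale
            if not hill_fixed:
                self.bse["hill"] = se[3]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Model-predicted percent interaction at concentrations `x` (µM)."""
        return _log_logistic(np.asarray(x, dtype=float), self.params[0],
                             self.params[1], self.params[2], self.hill)

    def summary(self) -> str:
        lines = [
            "Dose-response fit (log-logistic, "
            + ("Hill = 1 fixed)" if self.hill_fixed else "free Hill slope)"),
            "-" * 46,
            f"{'parameter':<10}{'estimate':>12}{'std err':>12}",
        ]
        rows = [("top", self.top), ("bottom", self.bottom), ("ic50", self.ic50)]
        if not self.hill_fixed:
            rows.append(("hill", self.hill))
        for name, val in rows:
            se = self.bse.get(name)
            lines.append(f"{name:<10}{val:>12.4g}{'' if se is None else format(se, '>12.3g')}")
        lines.append(f"RSS = {self.rss:.4g}    converged = {self.converged}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Semi-log concentration-response plot with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        ax.plot(d.concentrations, d.responses, "o", color="0.4", ms=4)
        xg = np.geomspace(d.concentrations.min(), d.concentrations.max(), 200)
        ax.plot(xg, self.predict(xg), "-", color="C3")
        ax.set_xscale("log")
        ax.set_xlabel("inhibitor (µM)")
        ax.set_ylabel("% interaction")
        ax.set_title(f"IC50 = {self.ic50:.3g} µM")
        return ax


def fit_ic50(data: DoseResponseData, fix_hill: bool = True) -> DoseResponseResults:
    """Fit the three-parameter log-logistic model; see :class:`DoseResponseModel`."""
    return DoseResponseModel(data).fit(fix_hill=fix_hill)
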