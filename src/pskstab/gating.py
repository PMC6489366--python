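"""Automated gating of flow-cytometry events into plasmid-bearing fractions.

The pipeline is: debris exclusion on the scatter channels, log10 transform
of the fluorescence channel, then a Gaussian mixture fit with 1 and 2
components selected by BIC.  With two resolved components the higher-mean
component is the plasmid-bearing (fluorescent) population and the fraction
is its responsibility-weighted share; with one component the whole sample is
assigned bearing or free by comparing the fitted mode to a reference
autofluorescence level.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .passaging import LossCurve
from .synthesize import EventTable

__all__ = ["GatingResult", "remove_debris", "classify_events", "batch_fractions"]

#: components closer than this (log10 decades) are treated as unresolved
MIN_MODE_SEPARATION = 0.2

#: default log10 autofluorescence level used to call single-component samples
DEFAULT_AUTOFLUORESCENCE = 1.5

MIN_EVENTS = 50


@dataclass(frozen=True)
class GatingResult:
    """Per-sample gating outcome."""

    fraction_bearing: float
    n_events_used: int
    n_debris_removed: int
    n_components_selected: int
    component_means: tuple[float, ...]  # log10 fluorescence
    component_scales: tuple[float, ...]
    threshold: float | None  # classification boundary, log10 units
    unresolved: bool = False  # two modes closer than MIN_MODE_SEPARATION


def remove_debris(events: EventTable, scatter_quantile: float = 0.05) -> EventTable:
    """Drop events below the given quantile on both scatter channels.

    Debris (cell fragments, electronic noise) sits at low forward and side
    scatter; an event is removed when it falls below the per-channel
    quantile cut on *either* channel.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    if not 0.0 <= scatter_quantile < 1.0:
        raise ValueError("scatter_quantile must lie in [0, 1)")
    if scatter_quantile == 0.0:
        return events
    fsc_cut = np.quantile(events.fsc, scatter_quantile)
    ssc_cut = np.quantile(events.ssc, scatter_quantile)
    keep = (events.fsc >= fsc_cut) & (events.ssc >= ssc_cut)
    if not np.any(keep):
        warnings.warn("all events removed as debris", stacklevel=2)
    return EventTable(
        fsc=events.fsc[keep],
        ssc=events.ssc[keep],
        fl1=events.fl1[keep],
        label=None if events.label is None else events.label[keep],
    )


def classify_events(
    events: EventTable,
    scatter_quantile: float = 0.05,
    autofluorescence: float = DEFAULT_AUTOFLUORESCENCE,
    random_state: int = 0,
) -> GatingResult:
    """Estimate the plasmid-bearing fraction of one sample.

    ``autofluorescence`` is the reference log10 fluorescence of a
    plasmid-free control; a single-component sample whose mode exceeds it
    by more than ``MIN_MODE_SEPARATION`` is called all-bearing, otherwise
    all-free.
    """
    n_in = len(events)
    gated = remove_debris(events, scatter_quantile)
    n_debris = n_in - len(gated)
    if len(gated) < MIN_EVENTS:
        raise ValueError(f"too few events after debris removal ({len(gated)} < {MIN_EVENTS})")
    if np.any(gated.fl1 <= 0):
        raise ValueError("non-positive fluorescence values")
    x = np.log10(gated.fl1).reshape(-1, 1)

    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=random_state)
        gm.fit(x)
        fits[k] = (gm.bic(x), gm)
    k_sel = min(fits, key=lambda k: fits[k][0])
    gm = fits[k_sel][1]
    means = gm.means_.ravel()
    scales = np.sqrt(gm.covariances_.ravel())

    unresolved = False
    if k_sel == 2 and abs(means[1] - means[0]) < MIN_MODE_SEPARATION:
        # populations unresolvable: fall back to the single-component call
        k_sel, gm = 1, fits[1][1]
        means = gm.means_.ravel()
        scales = np.sqrt(gm.covariances_.ravel())
        unresolved = True

    if k_sel == 2:
        hi = int(np.argmax(means))
        resp = gm.predict_proba(x)
        fraction = float(resp[:, hi].mean())
        # decision boundary between the two component means
        grid = np.linspace(means.min(), means.max(), 512).reshape(-1, 1)
        post_hi = gm.predict_proba(grid)[:, hi]
        cross = np.argmax(post_hi >= 0.5) if post_hi[-1] >= 0.5 else len(grid) - 1
        threshold = float(grid[cross, 0])
        order = np.argsort(means)
        return GatingResult(
            fraction_bearing=fraction,
            n_events_used=len(gated),
            n_debris_removed=n_debris,
            n_components_selected=2,
            component_means=tuple(means[order]),
            component_scales=tuple(scales[order]),
            threshold=threshold,
            unresolved=False,
        )
    mode = float(means[0])
    bearing = mode > autofluorescence + MIN_MODE_SEPARATION
    return GatingResult(
        fraction_bearing=1.0 if bearing else 0.0,
        n_events_used=len(gated),
        n_debris_removed=n_debris,
        n_components_selected=1,
        component_means=(mode,),
        component_scales=(float(scales[0]),),
        threshold=None,
        unresolved=unresolved,
    )


_KEY_RE = re.compile(r"^(?P<rep>.+?)[_\-:](?:p|passage)?(?P<pass>\d+)$")


def parse_sample_key(key: str) -> tuple[str, int]:
    """Split a sample key like ``rep01_p03`` into (replicate, passage)."""
    m = _KEY_RE.match(key)
    if not m:
        raise ValueError(f"cannot parse sample key {key!r} into (replicate, passage)")
    return m.group("rep"), int(m.group("pass"))


def batch_fractions(
    samples: dict[str, EventTable],
    scatter_quantile: float = 0.05,
    autofluorescence: float = DEFAULT_AUTOFLUORESCENCE,
) -> list[LossCurve]:
    """Gate a keyed batch of samples and assemble per-replicate loss curves.

    Keys must parse into (replicate, passage), e.g. ``rep01_p00``;
    duplicate (replicate, passage) pairs are rejected.  Output curves are
    passage-sorted and carry the post-gating event counts.
    """
    by_rep: dict[str, dict[int, GatingResult]] = {}
    for key, table in samples.items():
        rep, passage = parse_sample_key(key)
        if passage in by_rep.setdefault(rep, {}):
            raise ValueError(f"duplicate sample for replicate {rep!r}, passage {passage}")
        by_rep[rep][passage] = classify_events(
            table, scatter_quantile=scatter_quantile, autofluorescence=autofluorescence
        )
    curves = []
    for rep in sorted(by_rep):
        passages = sorted(by_rep[rep])
        results = [by_rep[rep][p] for p in passages]
        curves.append(
            LossCurve(
                replicate_id=rep,
                passage=np.array(passages),
                fraction=np.array([r.fraction_bearing for r in results]),
                n_events=np.array([r.n_events_used for r in results]),
            )
        )
    return curves
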