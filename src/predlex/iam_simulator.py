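"""Instrumented interactive-activation simulator of spoken word recognition.

The network has time-reduplicated phoneme units (one per phoneme symbol and
time slice) and word units (one per lexical entry and alignment slice at
which the word's full temporal extent fits).  Connectivity is the classic
interactive-activation scheme: bottom-up excitation from the input to
phoneme units, feedforward excitation from phoneme to word units, excitatory
feedback from word units to their constituent phoneme units, and lateral
inhibition within each layer between units with overlapping temporal extent.

The feature layer of the original architecture is abstracted away: bottom-up
input drives phoneme units directly through a ramped, overlapping timecourse
(:func:`encode_input`), which preserves every measured quantity (phoneme and
word activations, word-to-phoneme feedback flow).  Dynamics are synchronous,
clamped and fully deterministic; there is no stochastic component anywhere
in this module.

Every run is recorded as a :class:`SimulationTrace` holding all unit
activations per cycle plus three flow/activation totals: the transmitted
word-to-phoneme feedback (weight times positive sender activation, summed
over connections), and the raw sums of word-layer and phoneme-layer
activations (negative resting levels included, so layer totals are
typically negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .lexicon import Form, Lexicon, PhonemeInventory

__all__ = [
    "IAMParameters",
    "NetworkState",
    "InputTimecourse",
    "Network",
    "SimulationTrace",
    "build_network",
    "encode_input",
    "step",
    "run",
    "simulate",
    "input_onset_cycle",
    "phoneme_timecourse",
]


@dataclass(frozen=True)
class IAMParameters:
    """Connection weights, decay/rest levels and timing granularity.

    Defaults follow the classic public interactive-activation settings for
    spoken word recognition (phoneme-to-word 0.05, word-to-phoneme feedback
    0.03, within-layer inhibition 0.04/0.03, decay 0.03/0.05, rest -0.1 and
    -0.01, activation range [-0.3, 1.0], six slices per phoneme, input
    spread 3, 100 cycles).
    """

    excite_input_phoneme: float = 0.1
    excite_phoneme_word: float = 0.05
    feedback_word_phoneme: float = 0.03
    inhibit_phoneme_phoneme: float = 0.04
    inhibit_word_word: float = 0.03
    decay_phoneme: float = 0.03
    decay_word: float = 0.05
    rest_phoneme: float = -0.1
    rest_word: float = -0.01
    act_min: float = -0.3
    act_max: float = 1.0
    slices_per_phoneme: int = 6
    input_spread: int = 3
    n_cycles: int = 100

    def __post_init__(self) -> None:
        for name in (
            "excite_input_phoneme",
            "excite_phoneme_word",
            "feedback_word_phoneme",
            "inhibit_phoneme_phoneme",
            "inhibit_word_word",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("decay_phoneme", "decay_word"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for rest in (self.rest_phoneme, self.rest_word):
            if not (self.act_min < rest <= 0 <= self.act_max):
                raise ValueError("require act_min < rest <= 0 <= act_max")
        if self.slices_per_phoneme < 1:
            raise ValueError("slices_per_phoneme must be >= 1")
        if self.input_spread < 0:
            raise ValueError("input_spread must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class Network:
    """Static structure: unit layout, constituency and extents.

    ``constituency`` is a sparse (n_word_units, n_phoneme_units) matrix with
    a 1 wherever a word unit contains the flattened phoneme unit
    ``phoneme_index * n_slices + slice``.  A word of length L aligned at
    start slice ``a`` spans slices ``[a, a + L*spp + 2*spread - 1]`` and its
    i-th phoneme peaks at slice ``a + i*spp + spread`` (matching the input
    ramp peaks for the alignment ``a = 0``).

    The abstracted feature front-end can be swapped in by replacing
    ``encode_input``'s drive with feature-derived phoneme input; the network
    structure itself is front-end agnostic.
    """

    inventory: PhonemeInventory
    n_slices: int
    params: IAMParameters
    forms: list[Form]
    word_index: np.ndarray  # (n_word_units,) index into forms
    starts: np.ndarray  # (n_word_units,) first slice of extent
    ends: np.ndarray  # (n_word_units,) last slice of extent (inclusive)
    n_constituents: np.ndarray  # (n_word_units,) = word length
    constituency: sp.csr_matrix

    @property
    def n_phonemes(self) -> int:
        return len(self.inventory)

    @property
    def n_word_units(self) -> int:
        return len(self.word_index)

    def word_unit(self, form: Sequence[str], alignment: int) -> int:
        """Index of the unit for ``form`` aligned at start slice ``alignment``."""
        form = tuple(form)
        for u in range(self.n_word_units):
            if self.forms[self.word_index[u]] == form and self.starts[u] == alignment:
                return u
        raise KeyError(f"no word unit for {' '.join(form)} at alignment {alignment}")

    def constituent_slices(self, u: int) -> list[tuple[int, int]]:
        """(phoneme_index, slice) constituents of word unit ``u``."""
        spp = self.params.slices_per_phoneme
        spread = self.params.input_spread
        form = self.forms[self.word_index[u]]
        a = int(self.starts[u])
        return [
            (self.inventory.index(p), a + i * spp + spread)
            for i, p in enumerate(form)
        ]


@dataclass
class NetworkState:
    """Activations at one cycle; every value lies in [act_min, act_max]."""

    phoneme_act: np.ndarray  # (n_phonemes, n_slices)
    word_act: np.ndarray  # (n_word_units,)
    cycle: int = 0


@dataclass(frozen=True)
class InputTimecourse:
    """Bottom-up drive per (phoneme, slice), unfolding one slice per cycle.

    ``drive[p, s]`` is the eventual drive at slice ``s``; during the run a
    slice's drive switches on once the presentation has reached it (cycle >=
    slice index) and persists in the trace.  For a k-phoneme item the i-th
    phoneme's ramp onsets at slice ``(i-1)*spp`` (1-based i), peaks
    ``input_spread`` slices later and decays symmetrically, emulating
    sequential presentation with coarticulatory overlap.
    """

    drive: np.ndarray  # (n_phonemes, n_slices)

    def drive_at(self, cycle: int) -> np.ndarray:
        d = np.zeros_like(self.drive)
        upto = min(cycle + 1, self.drive.shape[1])
        if upto > 0:
            d[:, :upto] = self.drive[:, :upto]
        return d


@dataclass
class SimulationTrace:
    """Per-cycle record of all unit activations and flow totals."""

    network: Network
    item: Form
    phoneme_act: np.ndarray  # (n_cycles, n_phonemes, n_slices)
    word_act: np.ndarray  # (n_cycles, n_word_units)
    total_feedback: np.ndarray  # (n_cycles,)
    total_word_act: np.ndarray  # (n_cycles,)
    total_phoneme_act: np.ndarray  # (n_cycles,)

    @property
    def n_cycles(self) -> int:
        return self.phoneme_act.shape[0]


def extent_length(word_length: int, params: IAMParameters) -> int:
    return word_length * params.slices_per_phoneme + 2 * params.input_spread


def build_network(lex: Lexicon, params: IAMParameters, n_slices: int) -> Network:
    """Allocate phoneme and word units for every alignment that fits.

    One phoneme unit exists per (symbol, slice); one word unit per (entry,
    alignment) whose full temporal extent fits within ``n_slices``.
    """
    inv = lex.inventory
    forms = lex.forms
    for form in forms:
        for p in form:
            if p not in inv:
                raise ValueError(f"lexicon phoneme {p!r} outside the inventory")
    spp = params.slices_per_phoneme
    spread = params.input_spread

    word_index: list[int] = []
    starts: list[int] = []
    ends: list[int] = []
    n_const: list[int] = []
    rows: list[int] = []
    cols: list[int] = []
    u = 0
    for w, form in enumerate(forms):
        ext = extent_length(len(form), params)
        for a in range(0, n_slices - ext + 1):
            word_index.append(w)
            starts.append(a)
            ends.append(a + ext - 1)
            n_const.append(len(form))
            for i, p in enumerate(form):
                rows.append(u)
                cols.append(inv.index(p) * n_slices + a + i * spp + spread)
            u += 1

    constituency = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(u, len(inv) * n_slices),
    )
    return Network(
        inventory=inv,
        n_slices=n_slices,
        params=params,
        forms=forms,
        word_index=np.asarray(word_index, dtype=np.int64),
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        n_constituents=np.asarray(n_const, dtype=np.int64),
        constituency=constituency,
    )


def encode_input(
    item: Sequence[str],
    params: IAMParameters,
    inventory: PhonemeInventory,
    n_slices: int,
) -> InputTimecourse:
    """Triangular-ramp drive for a sequentially presented phoneme string.

    The i-th phoneme (1-based) peaks at slice ``(i-1)*spp + spread`` with
    value 1 and ramps linearly over +/- ``input_spread`` slices, so every
    phoneme carries the same total drive mass.  One new ramp begins every
    ``slices_per_phoneme`` slices.
    """
    form = tuple(item)
    if len(form) == 0:
        raise ValueError("item must be non-empty")
    spp = params.slices_per_phoneme
    spread = params.input_spread
    needed = (len(form) - 1) * spp + 2 * spread + 1
    if n_slices < needed:
        raise ValueError(
            f"n_slices={n_slices} too small for item of length {len(form)} "
            f"(need >= {needed})"
        )
    drive = np.zeros((len(inventory), n_slices))
    for i, p in enumerate(form):
        row = inventory.index(p)
        peak = i * spp + spread
        for s in range(peak - spread, peak + spread + 1):
            val = 1.0 - abs(s - peak) / (spread + 1)
            drive[row, s] = max(drive[row, s], val)
    return InputTimecourse(drive)


def input_onset_cycle(position: int, params: IAMParameters) -> int:
    """Cycle at which the input ramp for 1-based ``position`` begins."""
    return (position - 1) * params.slices_per_phoneme


def _layer_update(
    act: np.ndarray,
    net: np.ndarray,
    rest: float,
    decay: float,
    params: IAMParameters,
) -> np.ndarray:
    grow = net * (params.act_max - act)
    shrink = net * (act - params.act_min)
    delta = np.where(net > 0, grow, shrink) - decay * (act - rest)
    return np.clip(act + delta, params.act_min, params.act_max)


def step(
    state: NetworkState,
    drive: np.ndarray,
    network: Network,
    params: IAMParameters,
) -> tuple[NetworkState, float]:
    """One synchronous update; returns the new state and the feedback flow.

    Only positive activations transmit.  Net input to a phoneme unit is
    bottom-up drive plus word-to-phoneme feedback from every word unit
    containing it, minus lateral inhibition from other phoneme units within
    ``input_spread`` slices.  Net input to a word unit is excitation from
    its constituent phoneme units minus lateral inhibition from word units
    with overlapping extents.  Positive net input drives the unit toward
    act_max, negative net toward act_min, with passive decay toward rest and
    clamping to [act_min, act_max].

    The returned feedback flow is the transmitted word-to-phoneme excitation
    this cycle: weight times positive sender activation, summed over all
    word-to-phoneme connections (hence >= 0, and identically 0 when the
    feedback weight is 0).
    """
    p_act, w_act = state.phoneme_act, state.word_act
    p_pos = np.maximum(p_act, 0.0)
    w_pos = np.maximum(w_act, 0.0)
    S = network.n_slices

    # --- phoneme layer net input
    fb_flat = network.constituency.T @ w_pos
    feedback = params.feedback_word_phoneme * fb_flat.reshape(p_act.shape)
    total_feedback = float(params.feedback_word_phoneme * (w_pos @ network.n_constituents))

    colsum = p_pos.sum(axis=0)
    w = params.input_spread
    window = np.convolve(colsum, np.ones(2 * w + 1), mode="same")
    p_inhib = params.inhibit_phoneme_phoneme * (window[None, :] - p_pos)

    net_p = params.excite_input_phoneme * drive + feedback - p_inhib

    # --- word layer net input
    exc_w = params.excite_phoneme_word * (network.constituency @ p_pos.ravel())
    total_w = float(w_pos.sum())
    cum_end = np.cumsum(np.bincount(network.ends, weights=w_pos, minlength=S))
    cum_start = np.cumsum(np.bincount(network.starts, weights=w_pos, minlength=S))
    before = np.where(network.starts > 0, cum_end[network.starts - 1], 0.0)
    after = total_w - cum_start[network.ends]
    overlapping_others = total_w - before - after - w_pos
    net_w = exc_w - params.inhibit_word_word * overlapping_others

    new_p = _layer_update(p_act, net_p, params.rest_phoneme, params.decay_phoneme, params)
    new_w = _layer_update(w_act, net_w, params.rest_word, params.decay_word, params)
    return NetworkState(new_p, new_w, state.cycle + 1), total_feedback


def simulate(network: Network, item: Sequence[str], params: IAMParameters) -> SimulationTrace:
    """Run ``params.n_cycles`` cycles of ``item`` through a prebuilt network."""
    inp = encode_input(item, params, network.inventory, network.n_slices)
    state = NetworkState(
        phoneme_act=np.full((network.n_phonemes, network.n_slices), params.rest_phoneme),
        word_act=np.full(network.n_word_units, params.rest_word),
        cycle=0,
    )
    n = params.n_cycles
    p_rec = np.empty((n, network.n_phonemes, network.n_slices))
    w_rec = np.empty((n, network.n_word_units))
    fb_rec = np.empty(n)
    for t in range(n):
        state, fb = step(state, inp.drive_at(t), network, params)
        p_rec[t] = state.phoneme_act
        w_rec[t] = state.word_act
        fb_rec[t] = fb
    return SimulationTrace(
        network=network,
        item=tuple(item),
        phoneme_act=p_rec,
        word_act=w_rec,
        total_feedback=fb_rec,
        total_word_act=w_rec.sum(axis=1),
        total_phoneme_act=p_rec.sum(axis=(1, 2)),
    )


def default_n_slices(item_length: int, lex: Lexicon, params: IAMParameters) -> int:
    """Slice budget leaving room for words aligned anywhere over the item."""
    return (item_length + lex.max_length) * params.slices_per_phoneme + 2 * params.input_spread


def run(
    item: Sequence[str],
    lex: Lexicon,
    params: IAMParameters = IAMParameters(),
    n_slices: int | None = None,
) -> SimulationTrace:
    """Build the network for ``lex`` and simulate ``item``; deterministic."""
    if n_slices is None:
        n_slices = default_n_slices(len(item), lex, params)
    network = build_network(lex, params, n_slices)
    return simulate(network, item, params)


def phoneme_timecourse(
    trace: SimulationTrace,
    phoneme: str,
    position: int,
    item: Sequence[str],
    params: IAMParameters,
) -> np.ndarray:
    """Activation over cycles of ``phoneme``'s unit at the slice where the
    item's 1-based ``position`` is presented (the input ramp peak slice)."""
    if not 1 <= position <= len(item):
        raise ValueError(f"position {position} out of range for item of length {len(item)}")
    s = (position - 1) * params.slices_per_phoneme + params.input_spread
    if s >= trace.network.n_slices:
        raise KeyError(f"no phoneme unit at slice {s}")
    p = trace.network.inventory.index(phoneme)
    return trace.phoneme_act[:, p, s]
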