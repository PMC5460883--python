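"""Convenience drivers chaining normalization, the HMM, and block calling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import block_classify as bc
from .coverage_io import CoverageMatrix, ReferenceSummary, quantile_normalize, summarize_reference
from .hmm import EmissionParams, HmmParams, StateTrack, emission_probs, forward_backward

__all__ = ["decode_sample", "SampleResult", "states_frame"]


@dataclass
class SampleResult:
    """Decoded track plus blocks for one sample strain on one chromosome."""

    sample: str
    track: StateTrack
    ref: ReferenceSummary
    blocks: list = field(default_factory=list)

    @property
    def background_rate(self) -> float:
        return bc.background_rate(self.track.state)


def decode_sample(
    cov: CoverageMatrix,
    ref_samples: list[str],
    sample: str,
    normalize: bool = True,
    emission_params: EmissionParams | None = None,
    hmm_params: HmmParams | None = None,
    min_block_len: int = 50,
    strain: str = "",
    tissue: str = "",
) -> SampleResult:
    """Quantile normalize, summarize the reference, decode, call blocks."""
    norm = quantile_normalize(cov) if normalize else cov
    ref = summarize_reference(norm.subset(ref_samples))
    e = emission_probs(norm.column(sample), ref, emission_params)
    track = forward_backward(e, hmm_params, positions=norm.positions)
    blocks = bc.call_blocks(
        norm.positions,
        track.state,
        min_len=min_block_len,
        chrom=norm.chrom,
        strain=strain or sample,
        tissue=tissue,
    )
    return SampleResult(sample=sample, track=track, ref=ref, blocks=blocks)


def states_frame(chrom: str, track: StateTrack) -> pd.DataFrame:
    """States TSV layout: chrom, pos, P(down), P(stable), P(up), state."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": track.positions,
            "p_down": track.posterior[:, 0],
            "p_stable": track.posterior[:, 1],
            "p_up": track.posterior[:, 2],
            "state": np.asarray(track.state, dtype=int),
        }
    )
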