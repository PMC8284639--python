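"""Run-output containers and their HDF5 serialization."""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from gjcortex.network import NetworkGraph, load_graph, save_graph
from gjcortex.stimulus import StimulusTrace

__all__ = ["SpikeRecord", "WeightTrajectory", "TuningResult", "save_run", "load_run"]


@dataclass
class SpikeRecord:
    """Time-stamped cortical spikes plus the stimulus trace that drove them."""

    times: np.ndarray  # s, sorted
    cells: np.ndarray  # cell ids
    stimulus: StimulusTrace | None = None

    def __len__(self) -> int:
        return len(self.times)

    def spike_times_of(self, cell: int) -> np.ndarray:
        return self.times[self.cells == cell]

    def rates(self, n_cells: int, t_start: float, t_stop: float) -> np.ndarray:
        """Mean firing rate (Hz) per cell over [t_start, t_stop)."""
        if t_stop <= t_start:
            raise ValueError("empty window")
        sel = (self.times >= t_start) & (self.times < t_stop)
        counts = np.bincount(self.cells[sel], minlength=n_cells)
        return counts / (t_stop - t_start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell": self.cells, "time_s": self.times})


@dataclass
class WeightTrajectory:
    """Time-sampled snapshots of the plastic weight matrices.

    ``w_lgn`` has shape (n_snapshots, n_cells, n_lgn); ``w_ee`` and ``w_ei``
    have shape (n_snapshots, n_cells, n_cells), post x pre.  The last
    snapshot is always the final state of the run.
    """

    times: np.ndarray
    w_lgn: np.ndarray
    w_ee: np.ndarray
    w_ei: np.ndarray

    @property
    def final(self) -> dict[str, np.ndarray]:
        return {
            "w_lgn": np.asarray(self.w_lgn[-1], dtype=float),
            "w_ee": np.asarray(self.w_ee[-1], dtype=float),
            "w_ei": np.asarray(self.w_ei[-1], dtype=float),
        }


@dataclass
class TuningResult:
    """Per-cell tuning over the measurement sweep.

    ``curves`` holds the firing-rate responses (rows: cells, columns: the
    sweep stimuli) normalized by the maximum rate across all cells.  Cells
    with an all-zero response carry no orientation preference (OP): they are
    flagged unselective and their op/osi/width are NaN.
    """

    stimuli: np.ndarray  # sweep grid, input units
    curves: np.ndarray  # normalized responses (n_cells, n_stimuli)
    rates: np.ndarray  # raw rates, Hz
    op: np.ndarray  # preferred stimulus, NaN when undefined
    osi: np.ndarray
    width: np.ndarray  # FWHM in input units (circular)
    height: np.ndarray  # normalized peak
    selective: np.ndarray  # bool
    is_excitatory: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": np.arange(len(self.op)),
                "is_excitatory": self.is_excitatory,
                "op": self.op,
                "osi": self.osi,
                "width": self.width,
                "height": self.height,
                "selective": self.selective,
            }
        )


def save_run(
    path,
    graph: NetworkGraph,
    spikes: SpikeRecord,
    trajectory: WeightTrajectory | None = None,
    config_yaml: str | None = None,
) -> None:
    """Write a complete run (graph, spikes, weight snapshots) to HDF5."""
    with h5py.File(path, "w") as f:
        save_graph(f.create_group("graph"), graph)
        sg = f.create_group("spikes")
        sg.create_dataset("times", data=spikes.times)
        sg.create_dataset("cells", data=spikes.cells)
        if spikes.stimulus is not None:
            st = f.create_group("stimulus")
            st.create_dataset("onsets", data=spikes.stimulus.onsets)
            st.create_dataset("labels", data=spikes.stimulus.labels)
            st.create_dataset("durations", data=spikes.stimulus.durations)
        if trajectory is not None:
            tg = f.create_group("weights")
            tg.create_dataset("times", data=trajectory.times)
            tg.create_dataset("w_lgn", data=trajectory.w_lgn.astype(np.float32))
            tg.create_dataset("w_ee", data=trajectory.w_ee.astype(np.float32))
            tg.create_dataset("w_ei", data=trajectory.w_ei.astype(np.float32))
        if config_yaml is not None:
            f.attrs["config"] = config_yaml


def load_run(path):
    """Read back a run written by :func:`save_run`.

    Returns (graph, spikes, trajectory_or_None, config_yaml_or_None).
    """
    with h5py.File(path, "r") as f:
        graph = load_graph(f["graph"])
        stim = None
        if "stimulus" in f:
            stim = StimulusTrace(
                onsets=f["stimulus/onsets"][()],
                labels=f["stimulus/labels"][()],
                durations=f["stimulus/durations"][()],
            )
        spikes = SpikeRecord(
            times=f["spikes/times"][()], cells=f["spikes/cells"][()], stimulus=stim
        )
        traj = None
        if "weights" in f:
            traj = WeightTrajectory(
                times=f["weights/times"][()],
                w_lgn=f["weights/w_lgn"][()],
                w_ee=f["weights/w_ee"][()],
                w_ei=f["weights/w_ei"][()],
            )
        config = f.attrs.get("config")
    return graph, spikes, traj, config
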