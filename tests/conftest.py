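import numpy as np
import pytest

from polyion.chain import ChainSpec, Ensemble, Frame, IonRecord


@pytest.fixture
def three_bead_spec():
    return ChainSpec(n_residues=3, residue_labels=("E", "E", "E"),
                     bead_charge=(-1.0, -1.0, -1.0))


@pytest.fixture
def small_ensemble(three_bead_spec):
    """Two frames, three beads, one ion each, 50 Å box."""
    rng = np.random.default_rng(42)
    frames = []
    for k in range(2):
        coords = np.array([[10.0, 10, 10], [13.8, 10, 10], [17.6, 10, 10]])
        coords += rng.normal(0, 0.5, size=(3, 3))
        ions = [IonRecord("NA", 1, tuple(rng.uniform(0, 50, 3)), 2.3)]
        frames.append(Frame(chain_coords=coords, ions=ions, box_edge=50.0,
                            frame_index=k))
    return Ensemble(spec=three_bead_spec, frames=frames,
                    metadata={"spacing_unit": "frame"})


def random_ensemble(rng, n_res=5, n_frames=4, n_ions=2, box=60.0):
    labels = tuple(rng.choice(list("DEKRGS")) for _ in range(n_res))
    charges = tuple({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}.get(l, 0.0)
                    for l in labels)
    spec = ChainSpec(n_residues=n_res, residue_labels=labels,
                     bead_charge=charges)
    frames = []
    for k in range(n_frames):
        # random walk with 3.8 Å steps keeps the chain whole in the box
        steps = rng.normal(size=(n_res - 1, 3))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([rng.uniform(box * 0.3, box * 0.7, 3),
                            np.zeros((n_res - 1, 3))])
        coords[1:] = coords[0] + np.cumsum(steps, axis=0)
        ions = [IonRecord("NA" if rng.random() < 0.5 else "CL",
                          1 if rng.random() < 0.5 else -1,
                          tuple(rng.uniform(0, box, 3)), 2.3)
                for _ in range(n_ions)]
        frames.append(Frame(chain_coords=coords, ions=ions, box_edge=box,
                            frame_index=k))
    return Ensemble(spec=spec, frames=frames)
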