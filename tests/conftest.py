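import numpy as np
import pytest

from bilayerlab.datatypes import ChainTopology, FrameEnsemble
from bilayerlab import synthetic as synth


@pytest.fixture(scope="session")
def ordered_chain_system():
    """Medium chain fixture: |SCD| target 0.45, gauche 0.10, 2 frames."""
    spec = synth.SyntheticChainSpec(n_chains=64, n_carbons=16,
                                    order_param_target=0.45,
                                    gauche_prob=0.10, seed=11, n_frames=2)
    return synth.generate_chain_frames(spec), spec


def manual_chain_frames(positions, box=(5.0, 5.0, 5.0)):
    """Single-frame ensemble from an (n_atoms, 3) array."""
    pos = np.asarray(positions, dtype=float)
    return FrameEnsemble(pos[None], np.asarray(box, float)[None],
                         np.zeros(1))


def straight_chain_with_h(n_carbons=8, h_direction=(0.0, 0.0, 1.0),
                          z0=2.0, spacing=0.13):
    """A straight backbone along z with every C-H bond in one direction.

    Returns (FrameEnsemble, ChainTopology).
    """
    h_dir = np.asarray(h_direction, float)
    h_dir = h_dir / np.linalg.norm(h_dir)
    carbons = np.column_stack([np.full(n_carbons, 2.5),
                               np.full(n_carbons, 2.5),
                               z0 + spacing * np.arange(n_carbons)])
    hydrogens = np.vstack([carbons + 0.109 * h_dir, carbons + 0.109 * h_dir])
    pos = np.vstack([carbons, hydrogens])
    chains = [list(range(n_carbons))]
    ch_bonds = [(k, n_carbons + k) for k in range(n_carbons)] + \
               [(k, 2 * n_carbons + k) for k in range(n_carbons)]
    topo = ChainTopology(chains=chains, ch_bonds=ch_bonds,
                         dihedrals=ChainTopology.dihedrals_from_chains(chains),
                         leaflet=["upper"], headgroup_atoms=[0])
    return manual_chain_frames(pos), topo
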