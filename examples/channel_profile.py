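"""Central-channel geometry of a simulated hexameric ring.

A six-fold ring of tube-shaped subunits at 10 Å from the axis has a pore
radius of exactly 10 − 1.7 (carbon vdW) = 8.3 Å.  A second ring carries an
inward protrusion on each subunit — removing it widens the channel, the
mechanism by which truncating a channel-plugging C-terminal arm more than
doubles a pore.
"""

import numpy as np

from p4ring import channel_profile, ring_metrics
from p4ring.model import Atom, Chain, Residue, StructureModel
from p4ring.synthetic import RingSpec, make_ring

ring = make_ring(RingSpec(n_subunits=6, ring_radius=10.0, subunit_template="tube"))
met = ring_metrics(channel_profile(ring), ring)
print(f"plain ring: channel diameter {met.min_channel_diameter:.1f} A, "
      f"external diameter {met.external_diameter:.1f} A")

protruding = StructureModel("tmpl", [Chain("T", [
    Residue(i + 1, "ALA", atoms=[Atom("CA", "C", np.array([0.0, 0.0, z]))])
    for i, z in enumerate((-4.0, 0.0, 4.0))] + [
    Residue(4, "ALA", atoms=[Atom("CA", "C", np.array([-8.0, 0.0, 0.0]))])])])
full = make_ring(RingSpec(n_subunits=6, ring_radius=15.0, subunit_template=protruding))
met_full = ring_metrics(channel_profile(full), full)
trunc = full  # removing residue 4 of each chain = truncating the arm
trunc = StructureModel(full.id, [
    Chain(c.id, [r for r in c.residues if r.number != 4]) for c in full.chains])
met_trunc = ring_metrics(channel_profile(trunc), trunc)
print(f"ring with inward arms : channel {met_full.min_channel_diameter:.1f} A")
print(f"arms removed          : channel {met_trunc.min_channel_diameter:.1f} A "
      f"({met_trunc.min_channel_diameter / met_full.min_channel_diameter:.1f}x wider)")
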