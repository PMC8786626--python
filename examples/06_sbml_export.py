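"""Export the reaction network as SBML Level 3 for use in pathway tools."""
from pathlib import Path
from ampkmtor import baseline_parameters, build_network
from ampkmtor.sbml import write_sbml

net = build_network(baseline_parameters())
out = Path("model.sbml.xml")
write_sbml(net, out)
print(f"wrote {out} ({out.stat().st_size} bytes, "
      f"{len(net.reactions)} reactions, {len(net.species)} species)")
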