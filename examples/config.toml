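# Example simulation configuration: division-tracking design
# (doxycycline label shut-off at day 10, sampled at day 12).
n_founders = 40
horizon_steps = 24
snapshot_steps = [24]
seed = 7

[[interventions]]
kind = "DOXYCYCLINE"
start_step = 20

[[affinity_site_table]]
chain = "heavy"
position = 33
from_res = "W"
to_res = "L"
factor = 8.0

[[affinity_site_table]]
chain = "heavy"
position = 59
from_res = "K"
to_res = "R"
factor = 2.0

[[affinity_site_table]]
chain = "heavy"
position = 99
from_res = "Y"
to_res = "G"
factor = 2.0
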