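# Named side-view angle combinations for the ablation harness.
# "N-k" presets keep N of the eight angles; "7-k" drops the single angle
# (k-1)*45 degrees; "8" is the full un-ablated view set.
"8": [0, 45, 90, 135, 180, 225, 270, 315]
"7-1": [45, 90, 135, 180, 225, 270, 315]
"7-2": [0, 90, 135, 180, 225, 270, 315]
"7-3": [0, 45, 135, 180, 225, 270, 315]
"7-4": [0, 45, 90, 180, 225, 270, 315]
"7-5": [0, 45, 90, 135, 225, 270, 315]
"7-6": [0, 45, 90, 135, 180, 270, 315]
"7-7": [0, 45, 90, 135, 180, 225, 315]
"7-8": [0, 45, 90, 135, 180, 225, 270]
"6-1": [0, 45, 90, 135, 225, 270]
"6-2": [0, 45, 135, 180, 270, 315]
"6-3": [0, 45, 90, 135, 270, 315]
"6-4": [0, 45, 135, 180, 225, 270]
"6-5": [0, 135, 180, 225, 270, 315]
"6-6": [0, 90, 135, 180, 270, 315]
"5-1": [0, 135, 180, 270, 315]
"5-2": [0, 135, 180, 225, 315]
"5-3": [0, 90, 135, 270, 315]
"4-1": [0, 90, 180, 270]
"4-2": [45, 135, 225, 315]
"4-3": [0, 45, 135, 270]
"4-4": [90, 180, 225, 315]
"4-5": [0, 90, 135, 270]
"4-6": [0, 90, 180, 315]
"4-7": [0, 135, 180, 270]
"4-8": [0, 135, 180, 315]
"4-9": [0, 135, 270, 315]
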