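# Default ten-class three-channel taxonomy (RAD51 as structure centre).
# Classes 4 and 9 and the all-three-protein membership of classes 7-9 are
# fixed constraints; the remaining class boundaries are a reconstruction of
# an exhaustive enumeration over (single/multiple RAD51) x (absent/single/
# multiple 53BP1) x (absent/present BRCA1). Edit freely; the loader
# re-validates exhaustiveness and mutual exclusivity.
name: three_channel_default
site_channel: rad51
partner_channels:
- 53bp1
- brca1
encapsulation_channel: 53bp1
encapsulation:
  min_satellites: 3
  min_arc_deg: 180.0
  use_hull: true
  coplanar_tol_nm: 200.0
rules:
- class: 1
  site:
  - 1
  - 1
  partners:
    53bp1:
    - 0
    - 0
    brca1:
    - 0
    - 0
  encapsulated: null
- class: 2
  site:
  - 1
  - 1
  partners:
    53bp1:
    - 1
    - 1
    brca1:
    - 0
    - 0
  encapsulated: null
- class: 3
  site:
  - 1
  - 1
  partners:
    53bp1:
    - 2
    - null
    brca1:
    - 0
    - 0
  encapsulated: null
- class: 4
  site:
  - 2
  - null
  partners:
    53bp1:
    - 2
    - null
    brca1:
    - 0
    - 0
  encapsulated: null
- class: 5
  site:
  - 2
  - null
  partners:
    53bp1:
    - 1
    - 1
    brca1:
    - 0
    - 0
  encapsulated: null
- class: 6
  site:
  - 2
  - null
  partners:
    53bp1:
    - 0
    - 0
    brca1:
    - 0
    - 0
  encapsulated: null
- class: 7
  site:
  - 1
  - 1
  partners:
    53bp1:
    - 1
    - null
    brca1:
    - 1
    - null
  encapsulated: null
- class: 8
  site:
  - 2
  - null
  partners:
    53bp1:
    - 1
    - 1
    brca1:
    - 1
    - null
  encapsulated: null
- class: 8
  site:
  - 2
  - null
  partners:
    53bp1:
    - 2
    - null
    brca1:
    - 1
    - null
  encapsulated: false
- class: 9
  site:
  - 2
  - null
  partners:
    53bp1:
    - 2
    - null
    brca1:
    - 1
    - null
  encapsulated: true
- class: 10
  site:
  - 1
  - null
  partners:
    53bp1:
    - 0
    - 0
    brca1:
    - 1
    - null
  encapsulated: null
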