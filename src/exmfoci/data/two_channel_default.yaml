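# Default two-channel (BRCA1-site / 53BP1-partner) class taxonomy.
# Edit and pass via classify.rules_file to change the classification.
# Count conditions are [min, max] with null = unbounded.
name: two_channel_default
site_channel: brca1
partner_channels:
- 53bp1
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
  - null
  partners:
    53bp1:
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
  encapsulated: null
- class: 3
  site:
  - 2
  - null
  partners:
    53bp1:
    - 1
    - 1
  encapsulated: null
- class: 4
  site:
  - 2
  - null
  partners:
    53bp1:
    - 2
    - null
  encapsulated: null
- class: 4
  site:
  - 1
  - 1
  partners:
    53bp1:
    - 2
    - null
  encapsulated: false
- class: 5
  site:
  - 1
  - 1
  partners:
    53bp1:
    - 3
    - null
  encapsulated: true
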