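passive,saxatilis_male,saxatilis_1p5_male,arcana_male,compressa_male,obtusata_male,fabalis_male
saxatilis_female,1,1,1,0,0,1
saxatilis_male,1,1,1,0,1,0
saxatilis_1p5_male,1,1,1,0,0,0
arcana_female,1,0,1,0,0,0
arcana_male,1,1,1,0,1,0
compressa_female,1,0,0,1,0,0
compressa_male,0,0,0,1,1,0
obtusata_female,0,0,0,0,1,1
obtusata_male,1,0,1,1,1,0
fabalis_female,1,0,0,0,0,1
saxatilis_group_itc,1,1,1,0,0,0
obtusata_group_itc,0,0,0,0,1,1
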