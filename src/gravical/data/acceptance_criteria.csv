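liquid_class,subclass,volume_index,max_abs_dev_pct,max_cv_pct
serum,1,1,15,3
serum,1,2,10,3
serum,1,3,8,3
serum,2,1,7,3
serum,2,2,2,1
serum,2,3,1,0.75
serum,3,1,1,0.75
serum,3,2,0.5,0.75
serum,3,3,0.5,0.75
DMSO,2,1,10,3
DMSO,2,2,4,1
DMSO,2,3,2,0.75
water,2,1,7,3
water,2,2,1,1
water,2,3,0.5,0.75
water,3,1,0.5,0.75
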