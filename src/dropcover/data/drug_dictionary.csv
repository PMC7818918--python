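generic_name,drug_classes,is_fixed_combination,unit_bottle_volume,dosing_frequency
latanoprost,PG,0,2.5,once_daily
tafluprost,PG,0,2.5,once_daily
travoprost,PG,0,2.5,once_daily
bimatoprost,PG,0,2.5,once_daily
timolol,BB,0,5,twice_or_more_daily
carteolol,BB,0,5,twice_or_more_daily
dorzolamide,CAI,0,5,twice_or_more_daily
brinzolamide,CAI,0,5,twice_or_more_daily
brimonidine,AA,0,5,twice_or_more_daily
latanoprost/timolol,PG/BB,1,2.5,once_daily
travoprost/timolol,PG/BB,1,2.5,once_daily
tafluprost/timolol,PG/BB,1,2.5,once_daily
dorzolamide/timolol,CAI/BB,1,5,twice_or_more_daily
brinzolamide/timolol,CAI/BB,1,5,twice_or_more_daily
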