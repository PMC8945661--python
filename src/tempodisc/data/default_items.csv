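item_id,ss_amount,ll_amount,delay_days
1,840,2311,4
2,1089,2854,10
3,1412,3523,25
4,1831,4351,61
5,2374,5372,152
6,3077,6633,378
7,3990,8190,939
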