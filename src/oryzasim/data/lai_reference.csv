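cultivar,stage,mlai,slai_5,re_5,slai_10,re_10,slai_20,re_20,slai_30,re_30
YD6,tiller,3.56,3.83,7.58,3.92,10.11,3.94,10.67,3.95,10.96
YD6,jointing,6.31,6.88,9.09,6.95,10.14,6.97,10.46,6.98,10.62
YD6,flower,7.15,7.73,8.11,7.79,8.95,7.82,9.37,7.83,9.51
W14,tiller,3.23,3.53,9.29,3.61,11.76,3.63,12.38,3.64,12.69
W14,jointing,5.87,6.41,9.20,6.51,10.90,6.54,11.41,6.55,11.58
W14,flower,6.79,7.32,7.81,7.43,9.43,7.48,10.16,7.50,10.46
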