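structure,metric,value,units
PTV,Dmin,4932,cGy
PTV,Dmax,5259,cGy
PTV,Dmean,5131,cGy
PTV,D95%,5021,cGy
PTV,D2%,5251,cGy
PTV,D98%,4977,cGy
PTV,D50%,5134,cGy
PTV,HI,0.05,
PTV,CI,99.91,%
ipsilateral_lung,Dmean,1017,cGy
ipsilateral_lung,V500,38.80,%
ipsilateral_lung,V2000,19.56,%
ipsilateral_lung,V3000,12.54,%
heart,Dmean,438,cGy
heart,V3000,1.42,%
heart,V4000,0.30,%
spinal_cord,Dmax,81,cGy
spinal_cord_PRV,Dmax,88,cGy
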