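item_id,model,discrimination,step_1,step_2,step_3
1. Washing face,gpcm,2.18,-1.36,,
2. Brushing teeth,gpcm,1.73,-1.57,,
3. Climbing stairs (up and down 1 story),gpcm,1.14,-0.47,,
4. Walking outside (in the neighborhood for > 15 min),gpcm,0.8,-0.84,,
5. Taking public transportation,gpcm,0.52,-0.11,,
6. Preparing light meals,gpcm,1.28,0.68,,
7. Preparing ingredients for meals,gpcm,2.71,1.36,,
8. Washing dishes,gpcm,2.07,1.19,,
9. Trash disposal,gpcm,1.28,1.38,,
10. Taking out the trash,gpcm,1.45,1.5,,
11. Washing clothes,gpcm,2.12,1.23,,
12. Using a telephone,gpcm,0.83,-0.78,,
13. Social outings,gpcm,0.56,0.53,,
14. Reading newspapers,gpcm,0.56,0.48,,
15. Reading books,gpcm,0.57,1.13,,
16. Using a computer,gpcm,0.7,1.64,,
17. Art activities,gpcm,0.78,3.3,,
18. Playing board games/cards,gpcm,0.62,2.62,,
19. Singing karaoke,gpcm,0.63,2.24,,
20. Going to a spa (mainly for hot/cold water treatments),gpcm,0.96,2.64,,
21. Withdrawing money,gpcm,1.18,1.1,,
22. Volunteer work,gpcm,0.66,3.54,,
23. Gainful work,gpcm,0.73,2.53,,
24. Drinking,gpcm,0.82,-2.17,-1.12,
25. Eating,gpcm,1.06,-1.95,-0.78,
26. Bladder management,gpcm,3.23,-1.01,-0.36,
27. Bowel management,gpcm,3.02,-1.12,-0.24,
28. Getting up,gpcm,1.95,-1.6,-0.59,
29. Walking inside the house,gpcm,1.77,-1.31,-0.36,
30. Taking medicine on time,gpcm,0.93,-1.73,-0.09,
31. Watching television,gpcm,0.55,-2.48,-1.35,
32. Putting on clothes,gpcm,2.07,-0.83,-0.03,0.16
33. Taking off clothes,gpcm,2.36,-0.87,-0.15,0.04
34. Putting on trousers/skirts,gpcm,2.51,-0.77,-0.12,0.07
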